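"""Pipeline configuration: validated parameter blocks, YAML round trip."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import yaml

from .detect import DetectorParams
from .reference import PERICENTROMERE_FLANK_NT, SUBSTITUTION_RATE
from .simulate import SimulationSpec


@dataclasses.dataclass
class EnrichmentParams:
    """Delimitation defaults: CPM + pseudocount ratio at 10-kb bins, log2
    threshold 1, Mb-scale merging — tuned to produce contiguous Mb-scale
    centromere domains."""

    epsilon: float = 0.5
    bin_size: int = 10_000
    threshold: float = 1.0
    merge_gap: int = 500_000
    min_len: int = 500_000

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.merge_gap < 0 or self.min_len < 0:
            raise ValueError("merge_gap and min_len must be nonnegative")


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationSpec = dataclasses.field(default_factory=SimulationSpec)
    detector: DetectorParams = dataclasses.field(default_factory=DetectorParams)
    enrichment: EnrichmentParams = dataclasses.field(default_factory=EnrichmentParams)
    substitution_rate: float = SUBSTITUTION_RATE
    min_identity: float = 0.80
    pericentromere_flank_nt: dict = dataclasses.field(
        default_factory=lambda: dict(PERICENTROMERE_FLANK_NT)
    )
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        """Check every block before any stage runs."""
        self.simulation.validate()
        # DetectorParams validates in __post_init__; re-trigger for dict loads
        DetectorParams(**dataclasses.asdict(self.detector))
        self.enrichment.validate()
        if self.substitution_rate <= 0:
            raise ValueError("substitution rate must be positive")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["families"] = [
            dataclasses.asdict(f) for f in self.simulation.families
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .simulate import FamilyConsensus

        data = yaml.safe_load(Path(path).read_text())
        sim = data.get("simulation", {})
        fams = [FamilyConsensus(**f) for f in sim.pop("families", [])]
        if "centromere_interval" in sim:
            sim["centromere_interval"] = tuple(sim["centromere_interval"])
        if sim.get("satellite"):
            sim["satellite"] = tuple(sim["satellite"])
        cfg = cls(
            simulation=SimulationSpec(families=fams, **sim),
            detector=DetectorParams(**data.get("detector", {})),
            enrichment=EnrichmentParams(**data.get("enrichment", {})),
            substitution_rate=data.get("substitution_rate", SUBSTITUTION_RATE),
            min_identity=data.get("min_identity", 0.80),
            pericentromere_flank_nt=data.get(
                "pericentromere_flank_nt", dict(PERICENTROMERE_FLANK_NT)
            ),
            seed=data.get("seed", 0),
            outdir=data.get("outdir"),
        )
        cfg.validate()
        return cfg
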