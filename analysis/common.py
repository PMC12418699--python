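"""Shared study configuration for the numbered analysis drivers.

One synthetic wheat-like chromosome: a CENH3-enriched centromeric block
carrying young retrotransposon insertions and a satellite array, flanked
by pericentromeres with older insertions — the study conditions every
driver operates on.  All drivers read/write under results/.
"""

from pathlib import Path

import numpy as np

from cenarch.config import EnrichmentParams, PipelineConfig
from cenarch.simulate import SimulationSpec, random_family

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"


def study_families(seed: int = 2024):
    """Five consensus families mirroring the CRW1–CRW5 naming, Gypsy-heavy."""
    rng = np.random.default_rng(seed)
    superfams = ["Gypsy", "Gypsy", "Gypsy", "Copia", "unknown"]
    return [
        random_family(
            f"CRW{i + 1}", rng,
            superfamily=superfams[i],
            ltr_len=int(rng.integers(600, 1400)),
            internal_len=int(rng.integers(3000, 6000)),
            autonomous=i != 2,  # CRW3 (Quinta-like) is the non-autonomous one
        )
        for i in range(5)
    ]


def study_config(seed: int = 2024) -> PipelineConfig:
    spec = SimulationSpec(
        chrom_name="chr1",
        chrom_length=1_000_000,
        centromere_interval=(425_000, 575_000),
        n_elements_per_region={"centromeric": 12, "pericentromeric": 6, "arm": 2},
        age_distribution={
            "centromeric": ("uniform", 0.0, 0.6),
            "pericentromeric": ("uniform", 0.8, 2.0),
            "arm": ("uniform", 0.8, 2.0),
        },
        pericentromere_flank=100_000,
        satellite=(550, 20),
        families=study_families(seed),
        seed=seed,
        enrichment_factor=4.0,
        mean_depth=100.0,
        bin_size=5_000,
    )
    return PipelineConfig(
        simulation=spec,
        enrichment=EnrichmentParams(bin_size=5_000, merge_gap=50_000, min_len=50_000),
        seed=seed,
    )
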