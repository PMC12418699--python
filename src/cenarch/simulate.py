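"""Synthetic genomes with planted LTR retrotransposons and ChIP coverage.

The simulator emits the inputs the analysis consumes — a chromosome
sequence, ChIP/Input coverage tracks, a family consensus library — plus a
ground-truth record of everything planted, so that detection, dating,
delimitation and classification can be scored against known answers.

The mutational model is the one the molecular clock assumes: after
insertion the two long terminal repeats (LTRs) of an element accumulate
substitutions independently at rate ``r`` per site per year, so an element
of age ``t`` shows an expected pairwise divergence of ``2·r·t`` between its
LTRs.  Substitution events are Poisson per site; each event is a transition
with probability ``kappa/(kappa+2)`` and otherwise a uniformly chosen
transversion.  No indels are introduced by default.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from typing import Optional, Sequence

import numpy as np

from .enrichment import CoverageTrack

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclasses.dataclass(frozen=True)
class FamilyConsensus:
    """Consensus model of one retrotransposon family.

    The full-length element is ``ltr_seq + internal_seq + ltr_seq``; it must
    start with TG and end with CA (the canonical LTR termini) and fall in the
    structural size range a full-length element is allowed to occupy.
    """

    family_id: str
    superfamily: str  # Gypsy | Copia | unknown
    ltr_seq: str
    internal_seq: str
    autonomous: bool = True

    def __post_init__(self) -> None:
        if self.superfamily not in ("Gypsy", "Copia", "unknown"):
            raise ValueError(f"unknown superfamily: {self.superfamily}")
        if not (100 <= len(self.ltr_seq) <= 2000):
            raise ValueError("LTR length must be in [100, 2000] nt")
        full = self.full_sequence()
        if not (3000 <= len(full) <= 25000):
            raise ValueError("full element length must be in [3000, 25000] nt")
        if not (full.startswith("TG") and full.endswith("CA")):
            raise ValueError("element must start with TG and end with CA")

    def full_sequence(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq


@dataclasses.dataclass
class PlantedElement:
    """Ground-truth record of one planted element (final coordinates)."""

    chrom: str
    insert_pos: int  # 0-based start of the 5' LTR in the emitted sequence
    true_age: float  # years
    family_id: str
    tsd: str
    truncated: bool = False
    ltr_len: int = 0
    end: int = 0  # 0-based exclusive end of the element (3' LTR end)
    region: str = ""

    @property
    def true_age_ma(self) -> float:
        return self.true_age / 1e6


@dataclasses.dataclass
class SimulationSpec:
    """Full description of one synthetic chromosome; the seed fixes everything."""

    chrom_name: str = "chr1"
    chrom_length: int = 1_000_000
    centromere_interval: tuple[int, int] = (400_000, 600_000)
    n_elements_per_region: dict = dataclasses.field(
        default_factory=lambda: {"centromeric": 0, "pericentromeric": 0, "arm": 0}
    )
    age_distribution: dict = dataclasses.field(
        default_factory=lambda: {
            "centromeric": ("uniform", 0.0, 1.0),
            "pericentromeric": ("uniform", 0.5, 2.0),
            "arm": ("uniform", 0.5, 2.0),
        }
    )  # per-region sampler: ("point", ma) or ("uniform", lo_ma, hi_ma)
    substitution_rate: float = 1.3e-8  # /site/year
    kappa: float = 2.0
    enrichment_factor: float = 4.0
    mean_depth: float = 100.0
    bin_size: int = 10_000
    satellite: Optional[tuple[int, int]] = None  # (unit_len, n_units)
    pericentromere_flank: int = 150_000
    families: Sequence[FamilyConsensus] = ()
    seed: int = 0

    def validate(self) -> None:
        s, e = self.centromere_interval
        if not (0 <= s < e <= self.chrom_length):
            raise ValueError("centromere interval must lie within the chromosome")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.substitution_rate <= 0:
            raise ValueError("substitution rate must be positive")


@dataclasses.dataclass
class SimulationTruth:
    """Everything planted, in final (post-insertion) coordinates."""

    chrom: str
    chrom_length: int
    centromere: tuple[int, int]
    elements: list[PlantedElement]
    satellite_interval: Optional[tuple[int, int]] = None
    satellite_unit_len: Optional[int] = None


def _check_dna(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in _BASE_INDEX:
            raise ValueError(f"non-ACGT character {c!r} at position {i}")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT background sequence."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate_sequence(
    seq: str, expected_subs_per_site: float, kappa: float, rng_seed
) -> str:
    """Apply the per-site Poisson substitution process to ``seq``.

    Each site receives ``Poisson(expected_subs_per_site)`` substitution
    events; each event is a transition with probability ``kappa/(kappa+2)``,
    otherwise one of the two transversions uniformly.  Length is preserved.
    """
    if expected_subs_per_site < 0:
        raise ValueError("expected_subs_per_site must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    _check_dna(seq)
    if expected_subs_per_site == 0:
        return seq
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    counts = rng.poisson(expected_subs_per_site, size=len(seq))
    hit = np.nonzero(counts)[0]
    p_ts = kappa / (kappa + 2.0)
    out = list(seq)
    for i in hit:
        base = out[i]
        for _ in range(counts[i]):
            if rng.random() < p_ts:
                base = _TRANSITION[base]
            else:
                base = _TRANSVERSIONS[base][rng.integers(0, 2)]
        out[i] = base
    return "".join(out)


def sample_tsd(rng: np.random.Generator, min_len: int = 4, max_len: int = 20) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return random_sequence(length, rng)


def build_element(
    consensus: FamilyConsensus,
    age_years: float,
    r: float,
    kappa: float,
    rng: np.random.Generator,
    truncated: bool = False,
) -> tuple[str, int]:
    """Mutate the two LTR copies independently for ``age_years`` of divergence.

    Returns the element sequence and the LTR length.  A truncated element
    lacks its 3' LTR and can never be recovered as full-length.
    """
    lam = r * age_years
    ltr5 = mutate_sequence(consensus.ltr_seq, lam, kappa, rng)
    internal = consensus.internal_seq
    if truncated:
        return ltr5 + internal, len(consensus.ltr_seq)
    ltr3 = mutate_sequence(consensus.ltr_seq, lam, kappa, rng)
    return ltr5 + internal + ltr3, len(consensus.ltr_seq)


def plant_element(
    chrom_seq: str,
    pos: int,
    consensus: FamilyConsensus,
    age_years: float,
    r: float,
    kappa: float,
    rng_seed,
    chrom: str = "chr1",
    truncated: bool = False,
) -> tuple[str, PlantedElement]:
    """Insert one element at ``pos`` with a sampled target-site duplication.

    The TSD (4–20 nt) flanks the element on both sides, as retroviral
    integration leaves it.  Both LTR copies are mutated independently with
    expected ``r * age_years`` substitutions per site, so the expected
    pairwise divergence between them is ``2·r·age_years``.
    """
    if not (0 <= pos <= len(chrom_seq)):
        raise ValueError("insertion position outside sequence")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if age_years < 0:
        raise ValueError("age must be >= 0")
    element, ltr_len = build_element(consensus, age_years, r, kappa, rng, truncated)
    tsd = sample_tsd(rng)
    new_seq = chrom_seq[:pos] + tsd + element + tsd + chrom_seq[pos:]
    start = pos + len(tsd)
    record = PlantedElement(
        chrom=chrom,
        insert_pos=start,
        true_age=age_years,
        family_id=consensus.family_id,
        tsd=tsd,
        truncated=truncated,
        ltr_len=ltr_len,
        end=start + len(element),
    )
    return new_seq, record


def random_family(
    family_id: str,
    rng: np.random.Generator,
    superfamily: str = "Gypsy",
    ltr_len: int = 1000,
    internal_len: int = 4000,
    autonomous: bool = True,
) -> FamilyConsensus:
    """Draw a random consensus with canonical TG…CA termini."""
    ltr = "TG" + random_sequence(ltr_len - 4, rng) + "CA"
    internal = random_sequence(internal_len, rng)
    return FamilyConsensus(family_id, superfamily, ltr, internal, autonomous)


def _sample_age_years(sampler, rng: np.random.Generator) -> float:
    kind = sampler[0]
    if kind == "point":
        return float(sampler[1]) * 1e6
    if kind == "uniform":
        return float(rng.uniform(sampler[1], sampler[2])) * 1e6
    raise ValueError(f"unknown age sampler: {sampler!r}")


def _region_bounds(spec: SimulationSpec) -> dict[str, list[tuple[int, int]]]:
    cs, ce = spec.centromere_interval
    f = spec.pericentromere_flank
    peri = [(max(0, cs - f), cs), (ce, min(spec.chrom_length, ce + f))]
    arm = [(0, max(0, cs - f)), (min(spec.chrom_length, ce + f), spec.chrom_length)]
    return {
        "centromeric": [(cs, ce)],
        "pericentromeric": [(a, b) for a, b in peri if b > a],
        "arm": [(a, b) for a, b in arm if b > a],
    }


def simulate_genome(spec: SimulationSpec) -> tuple[dict, SimulationTruth]:
    """Build the chromosome: uniform background + planted elements + satellite.

    Insertions are planned at anchor positions in background coordinates
    (re-drawn on collision up to a retry cap), then applied left to right so
    every truth record carries final coordinates.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background = random_sequence(spec.chrom_length, rng)

    regions = _region_bounds(spec)
    # plan insertions: (anchor, kind, payload)
    plans: list[tuple[int, str, object]] = []
    anchors: list[int] = []
    min_gap = 100

    def draw_anchor(bounds: list[tuple[int, int]]) -> int:
        widths = np.array([b - a for a, b in bounds], dtype=float)
        for _ in range(1000):
            k = int(rng.choice(len(bounds), p=widths / widths.sum()))
            a, b = bounds[k]
            pos = int(rng.integers(a, b))
            if all(abs(pos - q) >= min_gap for q in anchors):
                anchors.append(pos)
                return pos
        raise RuntimeError("could not place insertion without overlap")

    if spec.satellite is not None:
        unit_len, n_units = spec.satellite
        cs, ce = spec.centromere_interval
        sat_anchor = (cs + ce) // 2
        anchors.append(sat_anchor)
        unit = random_sequence(unit_len, rng)
        plans.append((sat_anchor, "satellite", unit * n_units))

    for region, n in spec.n_elements_per_region.items():
        if n == 0:
            continue
        if not spec.families:
            raise ValueError("spec plants elements but has no families")
        bounds = regions[region]
        sampler = spec.age_distribution[region]
        for _ in range(n):
            anchor = draw_anchor(bounds)
            fam = spec.families[int(rng.integers(0, len(spec.families)))]
            age = _sample_age_years(sampler, rng)
            element, ltr_len = build_element(
                fam, age, spec.substitution_rate, spec.kappa, rng
            )
            tsd = sample_tsd(rng)
            plans.append(
                (anchor, "element", (tsd + element + tsd, fam.family_id, age, tsd, ltr_len))
            )

    plans.sort(key=lambda p: p[0])
    pieces: list[str] = []
    elements: list[PlantedElement] = []
    sat_interval = None
    prev = 0
    offset = 0
    for anchor, kind, payload in plans:
        pieces.append(background[prev:anchor])
        if kind == "satellite":
            sat_seq = payload
            sat_interval = (anchor + offset, anchor + offset + len(sat_seq))
            pieces.append(sat_seq)
            offset += len(sat_seq)
        else:
            insert_seq, family_id, age, tsd, ltr_len = payload
            start = anchor + offset + len(tsd)
            elem_len = len(insert_seq) - 2 * len(tsd)
            elements.append(
                PlantedElement(
                    chrom=spec.chrom_name,
                    insert_pos=start,
                    true_age=age,
                    family_id=family_id,
                    tsd=tsd,
                    ltr_len=ltr_len,
                    end=start + elem_len,
                )
            )
            pieces.append(insert_seq)
            offset += len(insert_seq)
        prev = anchor
    pieces.append(background[prev:])
    seq = "".join(pieces)

    insert_anchors = sorted(p[0] for p in plans)
    insert_lengths = {}
    for anchor, kind, payload in plans:
        insert_lengths[anchor] = (
            len(payload) if kind == "satellite" else len(payload[0])
        )

    def final_pos(x: int) -> int:
        shift = sum(insert_lengths[a] for a in insert_anchors[: bisect_right(insert_anchors, x)])
        return x + shift

    cs, ce = spec.centromere_interval
    truth = SimulationTruth(
        chrom=spec.chrom_name,
        chrom_length=len(seq),
        centromere=(final_pos(cs), final_pos(ce)),
        elements=elements,
        satellite_interval=sat_interval,
        satellite_unit_len=spec.satellite[0] if spec.satellite else None,
    )
    for el in elements:
        el.region = _classify_region(el, truth, spec)
    genome = {spec.chrom_name: seq}
    return genome, truth


def _classify_region(
    el: PlantedElement, truth: SimulationTruth, spec: SimulationSpec
) -> str:
    mid = (el.insert_pos + el.end) // 2
    cs, ce = truth.centromere
    if cs <= mid < ce:
        return "centromeric"
    f = spec.pericentromere_flank
    if cs - f - 30000 <= mid < ce + f + 30000:
        return "pericentromeric"
    return "arm"


def _no_detection_evidence(region: str, s0: int, e0: int, d: int, vic: int = 60) -> bool:
    """True when no placement near [s0, e0) carries TSD/motif evidence.

    Mirrors the detector's tiered evidence rules so a "no-evidence" decoy is
    guaranteed to be one: no joint TSD+motif placement within ±vic, and no
    motif or long TSD at the boundary itself.
    """
    from .detect import find_tsd, motif_mismatches

    n = len(region)
    for ds in range(-vic, vic + 1):
        for de in range(-vic, vic + 1):
            s, e = s0 + ds, e0 + de
            if s < 0 or e > n or s >= e:
                continue
            motif_ok = motif_mismatches(region, s, e, d, "TGCA") <= 1
            if motif_ok and find_tsd(region, s, e, 4, 20):
                return False
            if abs(ds) <= 3 and abs(de) <= 3:
                if motif_ok or find_tsd(region, s, e, 6, 20):
                    return False
    return True


def detection_fixture(
    seed: int = 0, n_elements: int = 10, r: float = 1.3e-8
) -> tuple[str, list[PlantedElement], list[tuple[str, int, int]]]:
    """Genome with compliant planted elements plus five structural decoys.

    The decoys each violate exactly one full-length constraint: LTRs below
    the minimum length, copies spaced beyond the maximum distance, copy
    identity below threshold, a missing 3' LTR (truncation), and an intact
    pair stripped of both TSD and terminal motif.  Families are cycled so
    same-family neighbours sit beyond the pairing distance and cannot seed
    cross-element pseudo-pairs.  Returns (sequence, planted truth, decoy
    (kind, start, end) records).
    """
    rng = np.random.default_rng(seed)
    fams = [
        random_family(
            f"FAM{i + 1}", rng,
            ltr_len=int(rng.integers(600, 1200)),
            internal_len=int(rng.integers(3000, 6000)),
        )
        for i in range(5)
    ]
    pieces: list[str] = []
    cursor = 0
    elements: list[PlantedElement] = []
    decoys: list[tuple[str, int, int]] = []

    def emit(s: str) -> int:
        nonlocal cursor
        pieces.append(s)
        start = cursor
        cursor += len(s)
        return start

    def spacer() -> None:
        emit(random_sequence(int(rng.integers(3000, 8001)), rng))

    ages_ma = rng.uniform(0.0, 1.0, size=n_elements)
    ages_ma[0] = 0.0  # keep one incipient element in every fixture
    for i, age_ma in enumerate(ages_ma):
        spacer()
        fam = fams[i % len(fams)]
        element, ltr_len = build_element(fam, age_ma * 1e6, r, 2.0, rng)
        tsd = sample_tsd(rng)
        emit(tsd)
        start = emit(element)
        elements.append(
            PlantedElement(
                chrom="fixture", insert_pos=start, true_age=age_ma * 1e6,
                family_id=fam.family_id, tsd=tsd, ltr_len=ltr_len,
                end=start + len(element),
            )
        )
        emit(tsd)

    # decoy 1: repeat copies far below the minimum LTR length
    spacer()
    rep = random_sequence(50, rng)
    start = emit(rep + random_sequence(4000, rng) + rep)
    decoys.append(("short_ltr", start, cursor))

    # decoy 2: valid LTR-sized copies spaced beyond the maximum distance
    spacer()
    ltr = random_sequence(800, rng)
    start = emit(ltr + random_sequence(29_200, rng) + ltr)
    decoys.append(("over_span", start, cursor))

    # decoy 3: copy identity well below the similarity threshold
    spacer()
    base = random_sequence(800, rng)
    c1 = mutate_sequence(base, 0.15, 2.0, rng)
    c2 = mutate_sequence(base, 0.15, 2.0, rng)
    start = emit(c1 + random_sequence(5000, rng) + c2)
    decoys.append(("low_identity", start, cursor))

    # decoy 4: truncated element (3' LTR lost) — nothing left to pair
    spacer()
    fam = fams[0]
    trunc, _ = build_element(fam, 0.2e6, r, 2.0, rng, truncated=True)
    tsd = sample_tsd(rng)
    start = emit(tsd + trunc + tsd)
    decoys.append(("truncated", start, cursor))

    # decoy 5: intact repeat pair with no TSD and broken TG…CA termini.
    # Termini are fixed to C/G runs so no small boundary shift can read a
    # TG…CA; the flanks (and, if interior coincidences persist, the repeat
    # itself) are redrawn until the region truly carries no evidence.
    element = d = None
    for attempt in range(60):
        if element is None or attempt % 10 == 9:
            bad_ltr = "CCCC" + random_sequence(int(rng.integers(600, 1100)), rng) + "GGGG"
            internal = random_sequence(int(rng.integers(3000, 5000)), rng)
            element = bad_ltr + internal + bad_ltr
            d = len(bad_ltr) + len(internal)
        left = random_sequence(int(rng.integers(3000, 8001)), rng)
        right = random_sequence(200, rng)
        region = left + element + right
        if _no_detection_evidence(region, len(left), len(left) + len(element), d):
            break
    else:
        raise RuntimeError("could not vet a no-evidence decoy")
    emit(left)
    start = emit(element)
    decoys.append(("no_evidence", start, cursor))
    emit(right)
    spacer()

    return "".join(pieces), elements, decoys


def simulate_chip(
    chrom_length: int,
    centromere: tuple[int, int],
    enrichment_factor: float,
    mean_depth: float,
    bin_size: int,
    rng_seed,
    chrom: str = "chr1",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Bin-level Poisson ChIP and Input coverage.

    Input bins are ``Poisson(mean_depth)`` everywhere; ChIP bins are
    ``Poisson(mean_depth * enrichment_factor)`` for bins whose midpoint
    falls inside the centromere, ``Poisson(mean_depth)`` elsewhere.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_bins = -(-chrom_length // bin_size)
    mids = np.arange(n_bins) * bin_size + bin_size / 2
    cs, ce = centromere
    inside = (mids >= cs) & (mids < ce)
    chip_mean = np.where(inside, mean_depth * enrichment_factor, mean_depth)
    chip = rng.poisson(chip_mean).astype(float)
    inp = rng.poisson(np.full(n_bins, mean_depth)).astype(float)
    return (
        CoverageTrack(chrom=chrom, bin_size=bin_size, values=chip, chrom_length=chrom_length),
        CoverageTrack(chrom=chrom, bin_size=bin_size, values=inp, chrom_length=chrom_length),
    )
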