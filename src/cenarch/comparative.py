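"""Comparative analytics over centromeric sequence and element ages.

Covers the downstream comparisons the centromere-evolution analysis runs:
window dot plots between (sub)genome centromeres, satellite monomer
identity heatmaps, insertion-age distributions (median/quartiles, Gaussian
KDE, incipient counts), Mann–Whitney U tests between age cohorts,
ancestral/derived region partitioning of a pericentromeric domain, per
region age summaries, and family-by-centromere copy tables with
superfamily percentage roll-ups.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .detect import reverse_complement
from .enrichment import CentromereCall, round_half_up

# ------------------------------------------------------------------ dot plot


@dataclasses.dataclass
class DotPlot:
    window: int
    min_identity: float
    matches: list  # (x_start_nt, y_start_nt, orientation, identity)


def _window_identity(a: str, b: str, max_frac_diff: float) -> Optional[float]:
    """Banded global identity of two equal-length windows; None if below band."""
    k = int(math.ceil(len(a) * max_frac_diff * 2))
    res = edlib.align(a, b, mode="NW", k=k)
    if res["editDistance"] < 0:
        return None
    return 1.0 - res["editDistance"] / len(a)


def dotplot(
    seq_a: str, seq_b: str, window: int = 500, min_identity: float = 0.85
) -> DotPlot:
    """Window-level similarity matrix between two sequences.

    Non-overlapping windows of ``seq_a`` are compared against all
    non-overlapping windows of ``seq_b`` in forward and reverse-complement
    orientation; pairs at or above ``min_identity`` are reported.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > min(len(seq_a), len(seq_b)):
        raise ValueError("window exceeds sequence length")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    a_windows = [
        (i, seq_a[i : i + window]) for i in range(0, len(seq_a) - window + 1, window)
    ]
    b_windows = [
        (j, seq_b[j : j + window]) for j in range(0, len(seq_b) - window + 1, window)
    ]
    band = 1.0 - min_identity
    matches = []
    for i, wa in a_windows:
        for j, wb in b_windows:
            ident = _window_identity(wa, wb, band)
            if ident is not None and ident >= min_identity:
                matches.append((i, j, "forward", ident))
            ident = _window_identity(wa, reverse_complement(wb), band)
            if ident is not None and ident >= min_identity:
                matches.append((i, j, "reverse", ident))
    return DotPlot(window=window, min_identity=min_identity, matches=matches)


# ----------------------------------------------------------- satellite array


@dataclasses.dataclass
class MonomerHeatmap:
    monomers: list
    identity: np.ndarray  # symmetric, diagonal 1.0
    remainder_len: int


def monomerize_and_heatmap(array_seq: str, unit_len: int) -> MonomerHeatmap:
    """Cut a tandem array into unit-length monomers and compare all pairs.

    The trailing remainder shorter than one unit is dropped but its length
    recorded.  Identity is global-alignment identity (gaps counted against).
    """
    if unit_len <= 0:
        raise ValueError("unit_len must be positive")
    if len(array_seq) < unit_len:
        raise ValueError("array shorter than one unit")
    array_seq = array_seq.upper()
    n_units = len(array_seq) // unit_len
    monomers = [array_seq[i * unit_len : (i + 1) * unit_len] for i in range(n_units)]
    remainder = len(array_seq) - n_units * unit_len
    m = np.eye(n_units)
    for i, j in itertools.combinations(range(n_units), 2):
        res = edlib.align(monomers[i], monomers[j], mode="NW", task="distance")
        ident = 1.0 - res["editDistance"] / unit_len
        m[i, j] = m[j, i] = ident
    return MonomerHeatmap(monomers=monomers, identity=m, remainder_len=remainder)


# -------------------------------------------------------- age distributions


@dataclasses.dataclass
class AgeSummary:
    group: str
    n: int
    median_ma: float
    q1_ma: float
    q3_ma: float
    grid: np.ndarray
    density: np.ndarray
    incipient_count: int


def age_distribution(
    ages: Sequence[float], group: str = "", bandwidth="silverman", grid_points: int = 512
) -> AgeSummary:
    """Summarise an insertion-age cohort (Ma).

    Gaussian KDE with Silverman bandwidth by default; the returned density
    is renormalised to integrate to one over the evaluation grid.
    Incipient elements are those of age exactly zero (identical LTRs).
    """
    ages = np.asarray(list(ages), dtype=float)
    if len(ages) == 0:
        raise ValueError("need at least one age")
    incipient = int(np.sum(ages == 0.0))
    median = float(np.median(ages))
    q1, q3 = (float(q) for q in np.percentile(ages, [25, 75]))
    if len(ages) < 2 or np.std(ages) == 0:
        # degenerate cohort: represent the point mass with a narrow Gaussian
        loc = float(ages[0]) if np.std(ages) == 0 else float(np.mean(ages))
        bw = 0.02
        grid = np.linspace(loc - 5 * bw, loc + 5 * bw, grid_points)
        density = np.exp(-0.5 * ((grid - loc) / bw) ** 2)
    else:
        kde = stats.gaussian_kde(ages, bw_method=bandwidth)
        bw = float(np.sqrt(kde.covariance[0, 0]))
        grid = np.linspace(ages.min() - 4 * bw, ages.max() + 4 * bw, grid_points)
        density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return AgeSummary(
        group=group, n=len(ages), median_ma=median, q1_ma=q1, q3_ma=q3,
        grid=grid, density=density, incipient_count=incipient,
    )


# ------------------------------------------------------------ Mann–Whitney U


def _u_statistic(pooled_ranks: np.ndarray, idx_x, nx: int) -> float:
    rx = float(pooled_ranks[list(idx_x)].sum())
    return rx - nx * (nx + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
) -> tuple[float, float]:
    """Mann–Whitney U test with midranks for ties.

    Exact p by full enumeration of all C(n, n_x) group assignments when the
    pooled size is at most 12 (or when forced with mode="exact"); otherwise
    a normal approximation with tie-corrected variance and continuity
    correction.  ``alternative`` is one of "less" (x shifted below y),
    "greater", "two-sided".  Returns (U_x, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(nx), nx)
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    n = nx + ny
    if mode == "exact" or (mode == "auto" and n <= 12):
        total = 0
        n_le = n_ge = 0
        for combo in itertools.combinations(range(n), nx):
            u = _u_statistic(ranks, combo, nx)
            total += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p_le, p_ge = n_le / total, n_ge / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p

    if mode not in ("auto", "normal"):
        raise ValueError(f"unknown mode: {mode}")
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u_obs, 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sd
        p = 2.0 * stats.norm.sf(z)
    return u_obs, min(1.0, float(p))


# -------------------------------------------------------- region partition

#: partition class -> conventional region number (ancestral coverage in one /
#: some / all accessions, hexaploid-derived only, or neither)
REGION_NUMBERING = {
    "ancestral_one": 1,
    "derived_only": 2,
    "ancestral_some": 3,
    "neither": 4,
    "ancestral_all": 5,
}


@dataclasses.dataclass
class RegionPartition:
    domain: tuple[int, int]
    segments: list  # (start, end, class)
    n_ancestral_sets: int
    numbering: dict = dataclasses.field(default_factory=lambda: dict(REGION_NUMBERING))

    def class_at(self, pos: int) -> Optional[str]:
        for s, e, cls in self.segments:
            if s <= pos < e:
                return cls
        return None


def partition_regions(
    ancestral_sets: Sequence[Sequence[tuple[int, int]]],
    derived: Sequence[tuple[int, int]],
    domain: tuple[int, int],
) -> RegionPartition:
    """Partition a domain by ancestral/derived CENH3 coverage.

    Each base is classed by how many ancestral accessions' enriched sets
    cover it (one / some / all), by derived-only coverage (enrichment found
    only in the derived polyploid), or as neither.  Contiguous same-class
    runs are emitted as segments that tile the domain exactly.
    """
    d0, d1 = domain
    if d1 <= d0:
        raise ValueError("empty domain")
    k = len(ancestral_sets)
    for ivset in list(ancestral_sets) + [derived]:
        for s, e in ivset:
            if s < d0 or e > d1:
                raise ValueError(f"interval [{s}, {e}) outside domain {domain}")

    cuts = {d0, d1}
    for ivset in list(ancestral_sets) + [derived]:
        for s, e in ivset:
            cuts.update((s, e))
    edges = sorted(cuts)

    def covered(ivset, pos) -> bool:
        return any(s <= pos < e for s, e in ivset)

    segments: list[tuple[int, int, str]] = []
    for s, e in zip(edges[:-1], edges[1:]):
        mid = (s + e) // 2
        n_anc = sum(1 for ivset in ancestral_sets if covered(ivset, mid))
        if n_anc == k and k > 0:
            cls = "ancestral_all"
        elif n_anc == 1:
            cls = "ancestral_one"
        elif n_anc > 1:
            cls = "ancestral_some"
        elif covered(derived, mid):
            cls = "derived_only"
        else:
            cls = "neither"
        if segments and segments[-1][2] == cls:
            segments[-1] = (segments[-1][0], e, cls)
        else:
            segments.append((s, e, cls))
    return RegionPartition(domain=domain, segments=segments, n_ancestral_sets=k)


def region_age_summary(
    dated: Sequence, partition: RegionPartition
) -> tuple[dict[str, AgeSummary], pd.DataFrame]:
    """Per-class age summaries plus pairwise Mann–Whitney tests.

    Elements are assigned to partition segments by midpoint; classes with
    no datable elements are omitted.  Returns ({class: AgeSummary}, tests)
    where tests has one row per class pair with U and p (two-sided).
    """
    by_class: dict[str, list[float]] = {}
    for de in dated:
        if not de.valid or de.age_ma is None or de.element is None:
            continue
        mid = (de.element.start + de.element.end) // 2
        cls = partition.class_at(mid)
        if cls is None:
            continue
        by_class.setdefault(cls, []).append(de.age_ma)
    summaries = {
        cls: age_distribution(ages, group=cls) for cls, ages in by_class.items()
    }
    rows = []
    for a, b in itertools.combinations(sorted(by_class), 2):
        u, p = mann_whitney_u(by_class[a], by_class[b], alternative="two-sided")
        rows.append({"class_a": a, "class_b": b, "U": u, "p": p})
    return summaries, pd.DataFrame(rows, columns=["class_a", "class_b", "U", "p"])


# ------------------------------------------------------------- copy tables


def superfamily_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentage of each superfamily over the total, one decimal half-up."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()}


def crw_copy_table(
    assignments: pd.DataFrame, centromere_calls: Sequence[CentromereCall]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Family-by-centromere copy counts and superfamily percentages.

    ``assignments`` needs columns chrom, start, end, family_id, superfamily.
    An element counts toward a centromere when its midpoint lies inside the
    call.  Returns (family x centromere count table, superfamily -> %).
    """
    cols = {"chrom", "start", "end", "family_id", "superfamily"}
    if len(assignments) and not cols.issubset(assignments.columns):
        raise ValueError(f"assignments must have columns {sorted(cols)}")
    families = sorted(assignments["family_id"].unique()) if len(assignments) else []
    call_names = [c.chrom for c in centromere_calls]
    table = pd.DataFrame(0, index=families, columns=call_names)
    for _, row in assignments.iterrows():
        mid = (row["start"] + row["end"]) // 2
        for call in centromere_calls:
            if call.chrom == row["chrom"] and call.start <= mid < call.end:
                table.loc[row["family_id"], call.chrom] += 1
                break
    if len(assignments):
        sf_counts = assignments["superfamily"].value_counts().to_dict()
        pct = superfamily_percentages(sf_counts)
    else:
        pct = {}
    return table, pct
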