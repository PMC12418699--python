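"""CENH3 ChIP enrichment: ratio tracks, centromere delimitation, summaries.

The functional centromere is delimited as the region where the histone
variant CENH3 is enriched in ChIP relative to Input.  Coverage is compared
bin-wise as log2(ChIP/Input) after counts-per-million scaling; maximal runs
of enriched bins, merged over short gaps and filtered by a minimum length,
form the candidate intervals, and the longest interval per chromosome is
the primary centromere call.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class CoverageTrack:
    """Binned read counts over one chromosome."""

    chrom: str
    bin_size: int
    values: np.ndarray
    chrom_length: Optional[int] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be nonnegative")
        if self.chrom_length is None:
            self.chrom_length = len(self.values) * self.bin_size

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class RatioTrack:
    """Per-bin log2((chip+eps)/(input+eps)) after CPM scaling."""

    chrom: str
    bin_size: int
    values: np.ndarray
    epsilon: float
    normalization: str = "cpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio track must be finite")


@dataclasses.dataclass
class CentromereCall:
    """One called CENH3-enriched interval (0-based half-open, nt)."""

    chrom: str
    start: int
    end: int
    mean_log2: float = float("nan")
    primary: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return round_half_up(self.length / 1e6, 1)


def compute_ratio_track(
    chip: CoverageTrack, input_track: CoverageTrack, epsilon: float = 0.5,
    normalize: bool = True,
) -> RatioTrack:
    """log2 enrichment of ChIP over Input with CPM library-size scaling.

    Both tracks are scaled to counts-per-million before the ratio, so
    library-depth differences cancel; the pseudocount keeps empty bins
    finite.  With ``normalize=False`` raw counts are compared directly.
    Note that under CPM an enriched domain spanning fraction f of the
    chromosome depresses the whole track by log2(1 + (fold-1)·f); for the
    Mb-scale centromeres of a full chromosome this is negligible.
    """
    if chip.chrom != input_track.chrom or chip.bin_size != input_track.bin_size:
        raise ValueError("chip and input tracks must share chromosome and bin size")
    if chip.n_bins != input_track.n_bins:
        raise ValueError("chip and input tracks must have the same number of bins")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    def cpm(v: np.ndarray) -> np.ndarray:
        total = v.sum()
        return v * (1e6 / total) if total > 0 else v

    c = cpm(chip.values) if normalize else chip.values
    i = cpm(input_track.values) if normalize else input_track.values
    values = np.log2((c + epsilon) / (i + epsilon))
    return RatioTrack(
        chrom=chip.chrom, bin_size=chip.bin_size, values=values, epsilon=epsilon,
        normalization="cpm" if normalize else "none",
    )


def call_enriched_intervals(
    track: RatioTrack,
    threshold: float = 1.0,
    merge_gap: int = 500_000,
    min_len: int = 500_000,
) -> list[CentromereCall]:
    """Delimit enriched intervals from a ratio track.

    Maximal runs of bins with value >= ``threshold`` (log2 units) are taken;
    runs separated by less than ``merge_gap`` nt are merged; merged runs
    shorter than ``min_len`` nt are dropped.  The longest surviving interval
    is flagged as the primary call for the chromosome.
    """
    above = track.values >= threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    bs = track.bin_size
    runs = [(int(s) * bs, int(e) * bs) for s, e in zip(starts, ends)]

    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    kept = [(s, e) for s, e in merged if e - s >= min_len]
    if not kept:
        return []
    calls = []
    longest = max(e - s for s, e in kept)
    primary_assigned = False
    for s, e in kept:
        bin_lo, bin_hi = s // bs, -(-e // bs)
        mean_log2 = float(track.values[bin_lo:bin_hi].mean())
        is_primary = (e - s == longest) and not primary_assigned
        primary_assigned = primary_assigned or is_primary
        calls.append(
            CentromereCall(chrom=track.chrom, start=s, end=e, mean_log2=mean_log2, primary=is_primary)
        )
    return calls


@dataclasses.dataclass
class SizeSummary:
    per_chromosome: pd.DataFrame
    per_subgenome: pd.DataFrame


def calls_from_mb_intervals(
    rows: Iterable[tuple[str, float, float]]
) -> list[CentromereCall]:
    """Build calls from (chrom, start_mb, end_mb) pseudomolecule positions."""
    return [
        CentromereCall(chrom=c, start=int(round(a * 1e6)), end=int(round(b * 1e6)))
        for c, a, b in rows
    ]


def summarize_centromeres(
    calls: list[CentromereCall], subgenome_map: dict[str, str]
) -> SizeSummary:
    """Per-chromosome lengths and per-subgenome min/max/mean (Mb, 1 decimal).

    Mb values are rounded half-up to one decimal; the subgenome mean is
    computed over the per-chromosome lengths.
    """
    rows = []
    for call in calls:
        if call.chrom not in subgenome_map:
            raise KeyError(f"chromosome {call.chrom} missing from subgenome map")
        rows.append(
            {
                "chrom": call.chrom,
                "subgenome": subgenome_map[call.chrom],
                "start_mb": round_half_up(call.start / 1e6, 1),
                "end_mb": round_half_up(call.end / 1e6, 1),
                "length_mb": call.length_mb,
            }
        )
    per_chrom = pd.DataFrame(rows)
    summaries = []
    for sg, grp in per_chrom.groupby("subgenome", sort=True):
        lengths = grp["length_mb"]
        summaries.append(
            {
                "subgenome": sg,
                "n": len(grp),
                "min_mb": round_half_up(float(lengths.min()), 1),
                "max_mb": round_half_up(float(lengths.max()), 1),
                "mean_mb": round_half_up(float(lengths.mean()), 1),
                "total_mb": round_half_up(float(lengths.sum()), 1),
            }
        )
    return SizeSummary(per_chromosome=per_chrom, per_subgenome=pd.DataFrame(summaries))


def signal_correlation(
    a: RatioTrack, b: RatioTrack, region: Optional[tuple[int, int]] = None
) -> tuple[float, float, int]:
    """Pearson correlation of two ratio tracks over ``region`` (or all bins).

    Returns (r, R^2, n_bins).  This is the replicate/lineage concordance
    statistic used to compare CENH3 localisation between samples.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("tracks must share bin size")
    n = min(len(a.values), len(b.values))
    x, y = a.values[:n], b.values[:n]
    if region is not None:
        lo = region[0] // a.bin_size
        hi = -(-region[1] // a.bin_size)
        x, y = x[lo:hi], y[lo:hi]
    if len(x) < 3:
        raise ValueError("need at least 3 bins for correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation region")
    r, _ = stats.pearsonr(x, y)
    return float(r), float(r * r), int(len(x))
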