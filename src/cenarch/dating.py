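"""Molecular dating of LTR retrotransposon insertions.

At insertion the two LTRs of an element are identical; they then diverge
independently under the host's neutral substitution rate.  The insertion
age therefore follows from their pairwise divergence: align the 5' and 3'
LTR copies globally, count transitions (P) and transversions (Q) over
ungapped columns, correct for multiple hits with the Kimura two-parameter
distance

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

and convert to time as age = K / (2r), with r the substitution rate per
site per year (default 1.3e-8).  An element whose LTRs are still identical
(K = 0) is "incipient" — inserted effectively at time zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

from Bio import Align

from .detect import FlLTRElement, extract_ltr_sequences
from .reference import SUBSTITUTION_RATE

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")


@dataclasses.dataclass(frozen=True)
class SubstitutionCounts:
    """Observed divergence fractions over ungapped aligned columns."""

    n_cols: int
    P: float  # transition fraction
    Q: float  # transversion fraction

    def __post_init__(self) -> None:
        if self.n_cols <= 0:
            raise ValueError("n_cols must be positive")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("P and Q must be nonnegative with P + Q <= 1")


@dataclasses.dataclass
class DatedElement:
    """An element with its divergence counts, K2P distance and age."""

    element: Optional[FlLTRElement]
    counts: Optional[SubstitutionCounts]
    K: Optional[float]  # substitutions/site; None when saturated
    age_ma: Optional[float]
    incipient: bool
    valid: bool
    flags: set = dataclasses.field(default_factory=set)
    family_id: str = ""
    superfamily: str = ""


def make_aligner(match: float = 2.0, mismatch: float = -2.0, gap: float = -3.0) -> Align.PairwiseAligner:
    """Global aligner with the detector-matched scoring (linear gaps).

    Gaps carry an infinitesimal extra cost so that alignments tying on the
    integer scores resolve toward substitution columns rather than gap
    pairs (a transposed base pair would otherwise score the same gapped as
    mismatched, silently deflating divergence counts).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap - 1e-4
    aligner.extend_gap_score = gap - 1e-4
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def align_ltr_pair(ltr5: str, ltr3: str, aligner: Optional[Align.PairwiseAligner] = None):
    """Optimal global alignment of the two LTR copies.

    Returns a pair of equal-length gapped strings.  Ties in the dynamic
    program are broken deterministically by taking the aligner's first
    reported optimum.
    """
    if not ltr5 or not ltr3:
        raise ValueError("LTR sequences must be non-empty")
    aligner = aligner or _DEFAULT_ALIGNER
    alignment = next(iter(aligner.align(ltr5.upper(), ltr3.upper())))
    a, b = str(alignment[0]), str(alignment[1])
    return a, b


def count_substitutions(alignment: tuple[str, str]) -> SubstitutionCounts:
    """Transition/transversion fractions over ungapped, unambiguous columns.

    Gap columns and columns containing non-ACGT characters are excluded
    from the column count (distmat-style).
    """
    a, b = alignment
    if len(a) != len(b):
        raise ValueError("alignment rows must have equal length")
    n_cols = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        n_cols += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n_cols == 0:
        raise ValueError("alignment has no ungapped columns")
    return SubstitutionCounts(n_cols=n_cols, P=ts / n_cols, Q=tv / n_cols)


def kimura2p(counts: SubstitutionCounts) -> float:
    """Kimura two-parameter distance; raises on saturation.

    Requires 1 - 2P - Q > 0 and 1 - 2Q > 0; outside that domain the
    divergence is saturated and no finite distance exists.
    """
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturated: K2P correction undefined for these P, Q")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0


def age_from_distance(K: float, r: float = SUBSTITUTION_RATE) -> float:
    """Insertion age in Ma from divergence: age = K / (2r)."""
    if K < 0:
        raise ValueError("K must be nonnegative")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * r) / 1e6


def date_ltr_pair(
    ltr5: str,
    ltr3: str,
    r: float = SUBSTITUTION_RATE,
    aligner: Optional[Align.PairwiseAligner] = None,
    element: Optional[FlLTRElement] = None,
) -> DatedElement:
    """Align, count, correct and convert one LTR pair to an age."""
    counts = count_substitutions(align_ltr_pair(ltr5, ltr3, aligner))
    try:
        K = kimura2p(counts)
    except ValueError:
        return DatedElement(
            element=element, counts=counts, K=None, age_ma=None,
            incipient=False, valid=False, flags={"saturated"},
        )
    incipient = counts.P == 0 and counts.Q == 0
    return DatedElement(
        element=element,
        counts=counts,
        K=round(K, 4),
        age_ma=round(age_from_distance(K, r), 2),
        incipient=incipient,
        valid=True,
    )


def date_elements(
    elements: Sequence[FlLTRElement],
    seq: str,
    r: float = SUBSTITUTION_RATE,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> list[DatedElement]:
    """Date every detected element from its genomic LTR copies.

    Saturated elements are retained with ``valid=False`` so downstream
    tables can report them; they carry no numeric age.
    """
    aligner = aligner or _DEFAULT_ALIGNER
    out = []
    for el in elements:
        ltr5, ltr3 = extract_ltr_sequences(el, seq)
        out.append(date_ltr_pair(ltr5, ltr3, r, aligner, element=el))
    return out
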