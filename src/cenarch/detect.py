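"""Ab initio detection of full-length LTR retrotransposons.

A full-length element is recognised purely from sequence structure: two
similar long terminal repeats (LTRs) of 100–2000 nt whose starts lie
3–25 kb apart, with pairwise identity >= 0.85, ideally flanked by a 4–20 nt
target-site duplication (TSD) and bounded by the TG…CA dinucleotide motif.

Detection proceeds seed-and-extend: exact 30-mer matches at a compatible
spacing seed an x-drop extension (match +2, mismatch −2, stop when the
running score drops more than 5 below its maximum); surviving repeat pairs
are refined against TSD/motif evidence within a ±60 nt vicinity of each
boundary and overlapping candidates are resolved keeping the best-supported
element.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class DetectorParams:
    """Structural constraints and scoring of the detector."""

    seed_len: int = 30
    xdrop: int = 5
    match: int = 2
    mismatch: int = -2
    indel: int = -3  # kept for parameter completeness; extension is ungapped
    min_ltr: int = 100
    max_ltr: int = 2000
    min_dist: int = 3000  # start of 5' LTR to start of 3' LTR
    max_dist: int = 25000
    min_similarity: float = 0.85
    min_tsd: int = 4
    max_tsd: int = 20
    motif: str = "TGCA"
    motif_mismatch_max: int = 1
    vicinity: int = 60
    overlap_mode: str = "best"
    require_evidence: bool = True

    def __post_init__(self) -> None:
        if self.min_ltr > self.max_ltr:
            raise ValueError("min_ltr must not exceed max_ltr")
        if self.min_dist > self.max_dist:
            raise ValueError("min_dist must not exceed max_dist")
        if not (0 < self.min_similarity <= 1):
            raise ValueError("min_similarity must be in (0, 1]")


@dataclasses.dataclass
class RawCandidate:
    """Repeat pair from seed-and-extend, before boundary refinement."""

    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    similarity: float
    score: int


@dataclasses.dataclass
class FlLTRElement:
    """One detected full-length LTR retrotransposon (0-based half-open)."""

    chrom: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    strand: str = "+"
    ltr_similarity: float = 0.0
    tsd: Optional[str] = None
    motif_ok: bool = False
    quality_flags: set = dataclasses.field(default_factory=set)

    @property
    def start(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]

    @property
    def element_span(self) -> int:
        return self.end - self.start

    @property
    def ltr_distance(self) -> int:
        """Start-of-5'LTR to start-of-3'LTR distance."""
        return self.ltr3[0] - self.ltr5[0]

    def overlaps(self, other: "FlLTRElement") -> bool:
        return self.start < other.end and other.start < self.end


def _xdrop_extend(seq: str, i: int, j: int, length: int, params: DetectorParams):
    """Extend an exact match at (i, j, length) in both directions, ungapped.

    Returns (s1, s2, ext_len, matches, score): the aligned copies are
    seq[s1:s1+ext_len] and seq[s2:s2+ext_len].
    """
    n = len(seq)
    score = params.match * length
    best = score

    # rightward
    right = 0
    r_best, r_best_matches = 0, 0
    matches = 0
    p, q = i + length, j + length
    s = 0
    while q + right < n:
        a, b = seq[p + right], seq[q + right]
        if a == b and a != "N":
            s += params.match
            matches += 1
        else:
            s += params.mismatch
        right += 1
        if s > r_best:
            r_best, r_best_matches = s, matches
        elif r_best - s > params.xdrop:
            break
    r_len = 0
    # recover extension length achieving r_best
    if r_best > 0:
        s, matches, r_len = 0, 0, 0
        for k in range(right):
            a, b = seq[p + k], seq[q + k]
            if a == b and a != "N":
                s += params.match
                matches += 1
            else:
                s += params.mismatch
            if s == r_best and matches == r_best_matches:
                r_len = k + 1
    # leftward
    left = 0
    l_best, l_best_matches = 0, 0
    s, matches = 0, 0
    while i - 1 - left >= 0:
        a, b = seq[i - 1 - left], seq[j - 1 - left]
        if a == b and a != "N":
            s += params.match
            matches += 1
        else:
            s += params.mismatch
        left += 1
        if s > l_best:
            l_best, l_best_matches = s, matches
        elif l_best - s > params.xdrop:
            break
    l_len = 0
    if l_best > 0:
        s, matches, l_len = 0, 0, 0
        for k in range(left):
            a, b = seq[i - 1 - k], seq[j - 1 - k]
            if a == b and a != "N":
                s += params.match
                matches += 1
            else:
                s += params.mismatch
            if s == l_best and matches == l_best_matches:
                l_len = k + 1

    ext_len = l_len + length + r_len
    total_matches = l_best_matches + length + r_best_matches
    total_score = l_best + params.match * length + r_best
    return i - l_len, j - l_len, ext_len, total_matches, total_score


def _diagonal_matches(seq: str, d: int, lo: int, hi: int) -> int:
    """Matching positions between seq[lo:hi] and seq[lo+d:hi+d]."""
    return sum(
        1 for p in range(lo, hi) if seq[p] == seq[p + d] and seq[p] != "N"
    )


def find_ltr_pairs(seq: str, params: DetectorParams = DetectorParams()) -> list[RawCandidate]:
    """Seed-and-extend scan for candidate LTR pairs.

    Exact ``seed_len``-mer matches whose offsets differ by a value in
    [min_dist, max_dist] are extended by ungapped x-drop alignment.
    Extension fragments on one diagonal are chained whenever the merged
    stretch still meets ``min_similarity`` — a diverged LTR can interrupt
    the x-drop walk with a short mismatch run without splitting the repeat.
    A pair is kept if both copies fall within the LTR length bounds, the
    copies do not overlap, the identity meets the threshold, and the copies
    are not dominated by short-period tandem repetition (a satellite array
    matches itself at every multiple of its unit length and would otherwise
    masquerade as an LTR pair).
    """
    seq = seq.upper()
    n = len(seq)
    k = params.seed_len
    if n < params.min_dist + params.min_ltr:
        return []

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    # tandem mask: a k-mer recurring at short periods at least twice in a
    # row (>= 3 copies) marks satellite-like repetition.  Two clustered
    # elements of one family can place LTR copies < min_dist apart, but
    # their occurrence chain alternates short and long gaps and never
    # produces two consecutive short ones.
    tandem = bytearray(n)
    by_diag: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for i, j1, j2 in zip(positions, positions[1:], positions[2:]):
            if j1 - i < params.min_dist and j2 - j1 < params.min_dist:
                for p in range(i, min(n, j2 + k)):
                    tandem[p] = 1
        for i, j in itertools.combinations(positions, 2):
            if params.min_dist <= j - i <= params.max_dist:
                by_diag.setdefault(j - i, []).append(i)

    candidates: list[RawCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    for d, starts in sorted(by_diag.items()):
        starts.sort()
        covered_to = -1
        frags: list[tuple[int, int, int]] = []  # (start, length, matches)
        for i in starts:
            if i <= covered_to:
                continue
            s1, _, ext_len, matches, _ = _xdrop_extend(seq, i, i + d, k, params)
            covered_to = max(covered_to, s1 + ext_len - 1)
            frags.append((s1, ext_len, matches))

        frags.sort()
        merged: list[tuple[int, int, int]] = []
        for s1, L, m in frags:
            if merged:
                ps, pL, _ = merged[-1]
                span_end = max(ps + pL, s1 + L)
                new_len = span_end - ps
                if new_len <= params.max_ltr:
                    new_m = _diagonal_matches(seq, d, ps, span_end)
                    if new_m / new_len >= params.min_similarity:
                        merged[-1] = (ps, new_len, new_m)
                        continue
            merged.append((s1, L, m))

        for s1, ext_len, matches in merged:
            if not (params.min_ltr <= ext_len <= params.max_ltr):
                continue
            if not (params.min_dist <= d <= params.max_dist):
                continue
            if s1 + ext_len > s1 + d:  # copies must not overlap
                continue
            identity = matches / ext_len
            if identity < params.min_similarity:
                continue
            if ext_len > 0 and sum(tandem[s1 : s1 + ext_len]) / ext_len > 0.5:
                continue  # short-period tandem repetition, not an LTR pair
            key = (s1, ext_len, d)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                RawCandidate(
                    ltr5=(s1, s1 + ext_len),
                    ltr3=(s1 + d, s1 + d + ext_len),
                    similarity=identity,
                    score=params.match * matches + params.mismatch * (ext_len - matches),
                )
            )
    candidates.sort(key=lambda c: (c.ltr5[0], c.ltr3[0]))
    return candidates


#: boundary slack (nt) within which weaker, single-line evidence is trusted
ANCHOR_SLACK = 3
#: minimum TSD length accepted without a corroborating motif
TSD_ONLY_MIN_LEN = 6


def motif_mismatches(seq: str, s: int, e: int, d: int, motif: str) -> int:
    """Mismatches against TG…CA over the termini of BOTH LTR copies.

    The two copies are tied through the repeat diagonal ``d`` (start of the
    3' LTR minus start of the 5' LTR): both copies must start TG (positions
    s and s+d) and end CA (positions e and e-d), eight bases in all.  This
    doubles the evidence a chance placement has to fake.
    """
    head, tail = motif[:2], motif[2:]
    mm = 0
    n = len(seq)
    for pos in (s, s + d):
        for k in range(2):
            if pos + k >= n or seq[pos + k] != head[k]:
                mm += 1
    for pos in (e, e - d):
        for k in range(2):
            if pos - 2 + k < 0 or pos - 2 + k >= n or seq[pos - 2 + k] != tail[k]:
                mm += 1
    return mm


def find_tsd(
    seq: str, s: int, e: int, min_len: int, max_len: int
) -> Optional[str]:
    """Longest exact direct repeat immediately flanking [s, e), or None."""
    for L in range(max_len, min_len - 1, -1):
        if s - L < 0 or e + L > len(seq):
            continue
        if seq[s - L : s] == seq[e : e + L]:
            return seq[s - L : s]
    return None


def refine_boundaries(
    candidate: RawCandidate, seq: str, params: DetectorParams = DetectorParams(), chrom: str = "chr1"
) -> FlLTRElement:
    """Shift element boundaries to the best TSD/motif-supported placement.

    Evidence is tiered: a placement carrying both a flanking TSD and the
    (copy-tied) TG…CA motif is trusted anywhere within ±vicinity of the
    provisional boundaries; motif-only placements are trusted only within
    a few nt of the extension boundary, and a TSD alone must be at least
    ``TSD_ONLY_MIN_LEN`` nt there — an unsupported 4-mer direct repeat
    arises by chance too often over a 2-D boundary search.  Among equal
    tiers the smallest shift wins; missing evidence is recorded in
    ``quality_flags``, never fatal.
    """
    seq = seq.upper()
    s0 = candidate.ltr5[0]
    e0 = candidate.ltr3[1]
    d = candidate.ltr3[0] - candidate.ltr5[0]
    vic = params.vicinity
    n = len(seq)

    def placement(ds: int, de: int):
        s, e = s0 + ds, e0 + de
        if s < 0 or e > n or s >= e or e - s > 2 * d:
            return None
        return s, e

    best = None  # (tier, ds, de, tsd, motif_ok)

    # tier 3: joint TSD + motif anywhere in the vicinity.  Placements are
    # scored by tsd_len - shift: sliding a boundary k nt off a true TSD
    # leaves a k-shorter suffix repeat at a k-smaller shift, so this score
    # is invariant along a genuine TSD, while a chance repeat far from the
    # extension boundary is penalised by its full shift.  Ties go to the
    # longer TSD (the untruncated placement), then the smaller shift.
    shifts = sorted(
        ((ds, de) for ds in range(-vic, vic + 1) for de in range(-vic, vic + 1)),
        key=lambda p: (abs(p[0]) + abs(p[1]), abs(p[0]), p[0], p[1]),
    )
    tier3 = []
    for ds, de in shifts:
        pl = placement(ds, de)
        if pl is None:
            continue
        s, e = pl
        if motif_mismatches(seq, s, e, d, params.motif) > params.motif_mismatch_max:
            continue
        tsd = find_tsd(seq, s, e, params.min_tsd, params.max_tsd)
        if tsd is not None:
            shift = abs(ds) + abs(de)
            tier3.append((len(tsd) - shift, len(tsd), -shift, ds, de, tsd))
    if tier3:
        _, _, _, ds, de, tsd = max(tier3)
        best = (3, ds, de, tsd, True)

    if best is None:
        # tier 2/1: single-line evidence, only near the extension boundary
        for ds, de in shifts:
            if abs(ds) > ANCHOR_SLACK or abs(de) > ANCHOR_SLACK:
                continue
            pl = placement(ds, de)
            if pl is None:
                continue
            s, e = pl
            motif_ok = (
                motif_mismatches(seq, s, e, d, params.motif)
                <= params.motif_mismatch_max
            )
            if motif_ok:
                best = (2, ds, de, None, True)
                break
            tsd = find_tsd(seq, s, e, max(params.min_tsd, TSD_ONLY_MIN_LEN), params.max_tsd)
            if tsd is not None and best is None:
                best = (1, ds, de, tsd, False)
    if best is None:
        best = (0, 0, 0, None, False)

    _, ds, de, tsd, motif_ok = best
    s, e = s0 + ds, e0 + de
    flags = set()
    if tsd is None:
        flags.add("no_tsd")
    if not motif_ok:
        flags.add("no_motif")
    # both copies have length (e - s) - d, tied through the diagonal;
    # similarity is recomputed over the refined copies so exact boundaries
    # of an undiverged element report identity 1.0
    copy_len = (e - s) - d
    matches = sum(
        1 for k in range(copy_len) if seq[s + k] == seq[s + d + k] and seq[s + k] != "N"
    )
    return FlLTRElement(
        chrom=chrom,
        ltr5=(s, e - d),
        ltr3=(s + d, e),
        ltr_similarity=matches / copy_len if copy_len > 0 else 0.0,
        tsd=tsd,
        motif_ok=motif_ok,
        quality_flags=flags,
    )


def _satisfies_bounds(el: FlLTRElement, params: DetectorParams) -> bool:
    len5 = el.ltr5[1] - el.ltr5[0]
    len3 = el.ltr3[1] - el.ltr3[0]
    return (
        params.min_ltr <= len5 <= params.max_ltr
        and params.min_ltr <= len3 <= params.max_ltr
        and params.min_dist <= el.ltr_distance <= params.max_dist
        and el.ltr5[1] <= el.ltr3[0]
        and el.ltr_similarity >= params.min_similarity
    )


def _evidence_tier(el: FlLTRElement) -> int:
    return (2 if el.motif_ok else 0) + (1 if el.tsd is not None else 0)


def resolve_overlaps(elements: list[FlLTRElement], mode: str = "best") -> list[FlLTRElement]:
    """Keep the best element among any mutually overlapping set.

    Best = strongest boundary evidence (TSD+motif > motif > TSD > none),
    then highest LTR similarity, then longer span, then leftmost.  Evidence
    outranks similarity so that a chance pairing between the LTRs of two
    neighbouring genuine elements — which shows LTR-like termini but never
    a target-site duplication — cannot displace the real elements it
    overlaps.
    """
    if mode != "best":
        raise ValueError(f"unknown overlap mode: {mode}")
    ranked = sorted(
        elements,
        key=lambda e: (-_evidence_tier(e), -e.ltr_similarity, -e.element_span, e.start),
    )
    kept: list[FlLTRElement] = []
    for el in ranked:
        if not any(el.overlaps(k) for k in kept):
            kept.append(el)
    kept.sort(key=lambda e: e.start)
    return kept


def detect_flltrs(
    seq: str, params: DetectorParams = DetectorParams(), chrom: str = "chr1"
) -> list[FlLTRElement]:
    """Full detection: find pairs, refine boundaries, filter, resolve overlaps.

    With ``require_evidence`` (default) candidates carrying neither a TSD
    nor the terminal motif are dropped — the integration-style filter that
    suppresses structural false positives.
    """
    raw = find_ltr_pairs(seq, params)
    refined = [refine_boundaries(c, seq, params, chrom) for c in raw]
    kept = []
    for el in refined:
        if not _satisfies_bounds(el, params):
            continue
        if params.require_evidence and el.tsd is None and not el.motif_ok:
            continue
        kept.append(el)
    return resolve_overlaps(kept, params.overlap_mode)


def extract_ltr_sequences(el: FlLTRElement, seq: str) -> tuple[str, str]:
    """The two LTR copies of a detected element, as uppercase strings."""
    return (
        seq[el.ltr5[0] : el.ltr5[1]].upper(),
        seq[el.ltr3[0] : el.ltr3[1]].upper(),
    )
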