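"""Exhaustive diagonal-scan validation of LTR-pair detection.

This scan is deliberately independent of the seed-and-extend detector: for
every admissible copy spacing ``d`` it compares ``seq[i]`` with
``seq[i+d]`` over the whole sequence and reports every window of at least
``min_ltr`` nt whose identity reaches ``min_similarity``.  It enumerates
all diagonals with no seeding, no scoring and no x-drop, so agreement with
the detector on small windows is a genuine cross-check.  Cost is
O(n · max_dist); intended for sequences up to a few tens of kb.
"""

from __future__ import annotations

import numpy as np

from .detect import DetectorParams


def scan_repeat_pairs(
    seq: str, params: DetectorParams = DetectorParams()
) -> list[tuple[int, int, int]]:
    """All (start, spacing d, window length) with windowed identity >= threshold.

    For each diagonal d in [min_dist, max_dist], a sliding window of
    ``min_ltr`` nt over the match indicator of seq[i] vs seq[i+d] flags the
    start positions of qualifying repeats; overlapping qualifying windows on
    one diagonal are merged into a single maximal run.
    """
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(s)
    w = params.min_ltr
    out: list[tuple[int, int, int]] = []
    for d in range(params.min_dist, min(params.max_dist, n - w) + 1):
        m = (s[: n - d] == s[d:]).astype(np.int32)
        if len(m) < w:
            continue
        c = np.concatenate(([0], np.cumsum(m)))
        frac = (c[w:] - c[:-w]) / w
        hits = np.nonzero(frac >= params.min_similarity)[0]
        if len(hits) == 0:
            continue
        # merge overlapping qualifying windows into maximal runs
        run_start = hits[0]
        prev = hits[0]
        for h in hits[1:]:
            if h <= prev + w:
                prev = h
            else:
                out.append((int(run_start), d, int(prev + w - run_start)))
                run_start = prev = h
        out.append((int(run_start), d, int(prev + w - run_start)))
    return out


def cluster_pairs(
    hits: list[tuple[int, int, int]], tol: int = 200
) -> list[tuple[int, int]]:
    """Collapse (start, d, len) hits into distinct repeat-pair loci.

    Two hits belong to the same locus when their starts and spacings are
    each within ``tol`` nt (nearby diagonals of one diverged repeat pair).
    Returns one representative (start, d) per locus.
    """
    loci: list[list[tuple[int, int]]] = []
    for start, d, _ in sorted(hits):
        placed = False
        for locus in loci:
            s0, d0 = locus[0]
            if abs(start - s0) <= tol and abs(d - d0) <= tol:
                locus.append((start, d))
                placed = True
                break
        if not placed:
            loci.append([(start, d)])
    return [locus[0] for locus in loci]


def agrees_with(
    detected: list[tuple[int, int]],
    oracle_loci: list[tuple[int, int]],
    tol: int = 200,
) -> bool:
    """True when detected (start, spacing) pairs and oracle loci match 1:1."""
    if len(detected) != len(oracle_loci):
        return False
    unmatched = list(oracle_loci)
    for s, d in detected:
        for k, (s0, d0) in enumerate(unmatched):
            if abs(s - s0) <= tol and abs(d - d0) <= tol:
                unmatched.pop(k)
                break
        else:
            return False
    return True
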