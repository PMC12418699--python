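"""Family assignment, K2P distance matrices and neighbor joining."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cenarch.classify import (
    FamilyEntry,
    FamilyLibrary,
    best_hit_assign,
    clade_report,
    neighbor_joining,
    pairwise_distance_matrix,
)
from cenarch.dating import SubstitutionCounts, kimura2p
from cenarch.simulate import mutate_sequence, random_sequence


def make_library(fams):
    return FamilyLibrary(
        entries=[FamilyEntry(f.family_id, f.superfamily, f.full_sequence()) for f in fams]
    )


class TestBestHitAssign:
    def test_exact_copy_assigned_at_identity_one(self, three_families):
        lib = make_library(three_families)
        fam, sf, ident = best_hit_assign(three_families[2].full_sequence(), lib)
        assert (fam, sf, ident) == ("CRW3", "Gypsy", 1.0)

    def test_random_sequence_falls_to_other(self, three_families):
        lib = make_library(three_families)
        fam, sf, ident = best_hit_assign(random_sequence(3300, np.random.default_rng(0)), lib)
        assert (fam, sf) == ("other", "unknown")
        assert ident < 0.80

    def test_half_ma_mutated_copies_recovered(self, three_families):
        # 0.5-Ma divergence (~0.65% per site) must not confuse families
        lib = make_library(three_families)
        rng = np.random.default_rng(1)
        lam = 1.3e-8 * 0.5e6
        correct = 0
        for i in range(100):
            true = three_families[i % 3]
            copy = mutate_sequence(true.full_sequence(), lam, 2.0, rng)
            fam, _, _ = best_hit_assign(copy, lib)
            correct += fam == true.family_id
        assert correct >= 95

    def test_threshold_monotone_to_other(self, three_families):
        lib = make_library(three_families)
        rng = np.random.default_rng(2)
        copy = mutate_sequence(three_families[0].full_sequence(), 0.05, 2.0, rng)
        fam_lo, _, ident = best_hit_assign(copy, lib)
        strict = FamilyLibrary(entries=lib.entries, min_identity=min(0.999, ident + 0.01))
        fam_hi, _, _ = best_hit_assign(copy, strict)
        assert fam_lo == "CRW1" and fam_hi == "other"

    def test_empty_inputs_rejected(self, three_families):
        with pytest.raises(ValueError):
            best_hit_assign("", make_library(three_families))


class TestDistanceMatrix:
    def test_identical_triplet_gives_zero_matrix(self):
        s = random_sequence(500, np.random.default_rng(3))
        D, flags = pairwise_distance_matrix([s, s, s])
        assert np.allclose(D.to_numpy(), 0.0)
        assert not flags

    def test_known_divergence_matches_kimura(self):
        # 500 columns: 50 transitions (A->G), 25 transversions (A->C)
        a = "A" * 500
        b = "G" * 50 + "C" * 25 + "A" * 425
        D, _ = pairwise_distance_matrix([a, b, "A" * 500])
        expected = kimura2p(SubstitutionCounts(500, 0.1, 0.05))
        assert D.iloc[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_saturated_pair_capped_and_flagged(self):
        # a/b at the K2P domain boundary (P=0.45, Q=0.10); a/c barely diverged
        a = "A" * 200
        b = ("G" * 45 + "C" * 10 + "A" * 45) * 2
        c = "G" * 2 + "A" * 198
        D, flags = pairwise_distance_matrix([a, b, c])
        assert "saturated_pairs" in flags
        finite = D.iloc[0, 2]
        assert finite < 0.05
        assert D.iloc[0, 1] >= 1.1 * finite - 1e-12


def caterpillar5(a, b, x, c, y, d, e):
    """Additive distances for the 5-taxon tree ((A,B),C,(D,E))."""
    taxa = list("ABCDE")
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    dist = {
        ("A", "B"): a + b, ("A", "C"): a + x + c, ("A", "D"): a + x + y + d,
        ("A", "E"): a + x + y + e, ("B", "C"): b + x + c, ("B", "D"): b + x + y + d,
        ("B", "E"): b + x + y + e, ("C", "D"): c + y + d, ("C", "E"): c + y + e,
        ("D", "E"): d + e,
    }
    for (i, j), v in dist.items():
        D.loc[i, j] = D.loc[j, i] = v
    return D


def quartet_split(path):
    """The cherry pairing minimising within-pair path sums (four-point rule)."""
    taxa = list(path.index)
    pairings = [
        ((taxa[0], taxa[1]), (taxa[2], taxa[3])),
        ((taxa[0], taxa[2]), (taxa[1], taxa[3])),
        ((taxa[0], taxa[3]), (taxa[1], taxa[2])),
    ]
    return min(
        pairings, key=lambda pr: path.loc[pr[0][0], pr[0][1]] + path.loc[pr[1][0], pr[1][1]]
    )


def least_squares_quartet(D):
    """Brute-force topology choice: least-squares branch fit on all 3 splits."""
    taxa = list(D.index)
    best = None
    for pairing in [
        ((0, 1), (2, 3)),
        ((0, 2), (1, 3)),
        ((0, 3), (1, 2)),
    ]:
        (i, j), (k, l) = pairing
        # unknowns: branch to each leaf (in pairing order) + internal edge
        rows, rhs = [], []
        pos = {t: p for p, t in enumerate([i, j, k, l])}
        for (u, v) in itertools.combinations([i, j, k, l], 2):
            row = [0.0] * 5
            row[pos[u]] = 1.0
            row[pos[v]] = 1.0
            same_side = {u, v} == {i, j} or {u, v} == {k, l}
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            rhs.append(D.iloc[u, v])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        fitted = np.array(rows) @ sol
        rss = float(np.sum((fitted - np.array(rhs)) ** 2))
        split = ((taxa[i], taxa[j]), (taxa[k], taxa[l]))
        if best is None or rss < best[0]:
            best = (rss, split)
    return best[1]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame(
            [[0, 2, 3], [2, 0, 4], [3, 4, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = neighbor_joining(D)
        path = tree.path_lengths()
        assert np.allclose(path.to_numpy(), D.to_numpy())
        # star branches (dAB+dAC-dBC)/2 etc.
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additive_four_taxon_matrix_reproduced_exactly(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d, m = rng.uniform(0.5, 4.0, size=5)
        taxa = list("ABCD")
        D = pd.DataFrame(0.0, index=taxa, columns=taxa)
        dist = {
            ("A", "B"): a + b, ("C", "D"): c + d, ("A", "C"): a + m + c,
            ("A", "D"): a + m + d, ("B", "C"): b + m + c, ("B", "D"): b + m + d,
        }
        for (i, j), v in dist.items():
            D.loc[i, j] = D.loc[j, i] = v
        tree = neighbor_joining(D)
        path = tree.path_lengths()
        assert np.abs(path.to_numpy() - D.to_numpy()).max() < 1e-9
        assert sorted(map(sorted, quartet_split(path))) == sorted(
            map(sorted, least_squares_quartet(D))
        )

    @pytest.mark.parametrize("seed", [5, 6])
    def test_additive_five_taxon_matrix_reproduced_exactly(self, seed):
        rng = np.random.default_rng(seed)
        D = caterpillar5(*rng.uniform(0.5, 3.0, size=7))
        tree = neighbor_joining(D)
        assert np.abs(tree.path_lengths().to_numpy() - D.to_numpy()).max() < 1e-9

    def test_two_taxon_degenerate_handled(self):
        D = pd.DataFrame([[0, 3], [3, 0]], index=list("AB"), columns=list("AB"), dtype=float)
        tree = neighbor_joining(D)
        assert "degenerate_two_taxa" in tree.flags
        assert tree.path_lengths().loc["A", "B"] == pytest.approx(3.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCladeReport:
    def test_elements_follow_nearest_reference(self, three_families):
        rng = np.random.default_rng(7)
        refs = {f"ref_{f.family_id}": f.family_id for f in three_families}
        seqs, ids = [], []
        for f in three_families:
            ids.append(f"ref_{f.family_id}")
            seqs.append(f.ltr_seq)
        truth = {}
        for i in range(9):
            f = three_families[i % 3]
            eid = f"el{i}"
            ids.append(eid)
            seqs.append(mutate_sequence(f.ltr_seq, 1.3e-8 * 0.5e6, 2.0, rng))
            truth[eid] = f.family_id
        D, _ = pairwise_distance_matrix(seqs, ids)
        tree = neighbor_joining(D)
        report = clade_report(tree, refs)
        agree = sum(report[e] == fam for e, fam in truth.items())
        assert agree >= 8  # >= ~90 % agreement on a young cohort

    def test_reference_required(self, three_families):
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 2], [2, 2, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        with pytest.raises(ValueError):
            clade_report(neighbor_joining(D), {})
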