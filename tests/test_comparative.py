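"""Dot plots, satellite monomers, age distributions, U tests, partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cenarch.comparative import (
    age_distribution,
    crw_copy_table,
    dotplot,
    mann_whitney_u,
    monomerize_and_heatmap,
    partition_regions,
    region_age_summary,
    superfamily_percentages,
)
from cenarch.dating import DatedElement, SubstitutionCounts
from cenarch.detect import FlLTRElement, reverse_complement
from cenarch.enrichment import CentromereCall
from cenarch.simulate import mutate_sequence, random_sequence


class TestDotplot:
    def test_self_comparison_gives_full_forward_diagonal(self):
        s = random_sequence(8000, np.random.default_rng(0))
        dp = dotplot(s, s, window=500)
        fwd = {(m[0], m[1]) for m in dp.matches if m[2] == "forward"}
        assert {(i, i) for i in range(0, 7501, 500)} <= fwd
        # forward matches symmetric under (x, y) -> (y, x)
        assert all((y, x) in fwd for x, y in fwd)

    def test_reverse_complement_gives_antidiagonal(self):
        s = random_sequence(5000, np.random.default_rng(1))
        dp = dotplot(s, reverse_complement(s), window=500)
        rev = [(m[0], m[1]) for m in dp.matches if m[2] == "reverse"]
        assert len(rev) == 10
        assert all(x + y == 4500 for x, y in rev)

    def test_unrelated_sequences_give_no_matches(self):
        rng = np.random.default_rng(2)
        a, b = random_sequence(50_000, rng), random_sequence(50_000, rng)
        assert dotplot(a, b, window=500, min_identity=0.85).matches == []

    def test_window_validation(self):
        with pytest.raises(ValueError):
            dotplot("ACGT" * 100, "ACGT" * 100, window=0)
        with pytest.raises(ValueError):
            dotplot("ACGT", "ACGT", window=500)


class TestMonomerHeatmap:
    def test_identical_units_all_one(self):
        unit = random_sequence(550, np.random.default_rng(3))
        mh = monomerize_and_heatmap(unit * 20, 550)
        assert len(mh.monomers) == 20
        assert np.allclose(mh.identity, 1.0)
        assert mh.remainder_len == 0

    def test_remainder_recorded(self):
        unit = random_sequence(566, np.random.default_rng(4))
        mh = monomerize_and_heatmap(unit * 5 + random_sequence(100, np.random.default_rng(5)), 566)
        assert len(mh.monomers) == 5
        assert mh.remainder_len == 100

    def test_mutated_units_show_expected_identity(self):
        # each copy mutated at ~2 % -> off-diagonal identity ~ 0.96
        rng = np.random.default_rng(6)
        unit = random_sequence(550, rng)
        array = "".join(mutate_sequence(unit, 0.02, 2.0, rng) for _ in range(10))
        mh = monomerize_and_heatmap(array, 550)
        off = mh.identity[~np.eye(10, dtype=bool)]
        assert float(off.mean()) == pytest.approx(0.96, abs=0.01)


class TestAgeDistribution:
    def test_single_age(self):
        s = age_distribution([1.0])
        assert s.median_ma == 1.0 and s.incipient_count == 0 and s.n == 1

    def test_all_incipient(self):
        s = age_distribution([0.0] * 7)
        assert s.incipient_count == 7

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(7)
        s = age_distribution(rng.exponential(0.5, 300))
        assert float(np.trapezoid(s.density, s.grid)) == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_mixture_shows_both_modes(self):
        rng = np.random.default_rng(8)
        ages = np.concatenate([rng.normal(0.1, 0.02, 250), rng.normal(1.0, 0.1, 250)])
        s = age_distribution(ages)
        d = s.density
        peaks = [
            s.grid[i]
            for i in range(1, len(d) - 1)
            if d[i] > d[i - 1] and d[i] > d[i + 1] and d[i] > 0.1 * d.max()
        ]
        assert any(abs(p - 0.1) < 0.05 for p in peaks)
        assert any(abs(p - 1.0) < 0.05 for p in peaks)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            age_distribution([])


class TestMannWhitney:
    def test_fully_separated_one_sided_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(0.05)  # 1 / C(6,3)

    def test_identical_multisets_symmetric(self):
        x = [1, 2, 3, 4]
        u, p = mann_whitney_u(x, list(x), alternative="two-sided")
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p >= 0.99

    def test_constant_data_returns_p_one(self):
        _, p = mann_whitney_u([5, 5, 5], [5, 5], alternative="two-sided")
        assert p == 1.0

    def test_exact_vs_normal_agreement_at_n8(self):
        rng = np.random.default_rng(9)
        worst = 0.0
        for _ in range(100):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 8)
            _, p_ex = mann_whitney_u(x, y, alternative="two-sided", mode="exact")
            _, p_no = mann_whitney_u(x, y, alternative="two-sided", mode="normal")
            worst = max(worst, abs(p_ex - p_no))
        assert worst <= 0.02

    @given(
        nx=st.integers(2, 5),
        ny=st.integers(2, 5),
        seed=st.integers(0, 10_000),
        alt=st.sampled_from(["less", "greater", "two-sided"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_matches_scipy_enumeration_without_ties(self, nx, ny, seed, alt):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1, nx + ny + 1, dtype=float))
        x, y = vals[:nx], vals[nx:]
        u, p = mann_whitney_u(x, y, alternative=alt, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative=alt.replace("-sided", "-sided"), method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)


class TestPartition:
    def test_three_accession_example(self):
        anc = [[(10, 12)], [(10, 12)], [(10, 12)]]
        part = partition_regions(anc, [(14, 16)], (8, 20))
        classes = {(s, e): c for s, e, c in part.segments}
        assert classes[(10, 12)] == "ancestral_all"
        assert classes[(14, 16)] == "derived_only"
        assert classes[(12, 14)] == "neither"
        assert part.numbering["derived_only"] == 2

    def test_single_accession_coverage_is_ancestral_one(self):
        part = partition_regions([[(5, 8)], [], []], [], (0, 10))
        assert ("ancestral_one" in {c for _, _, c in part.segments})

    def test_empty_derived_set(self):
        part = partition_regions([[(2, 4)]], [], (0, 10))
        assert all(c != "derived_only" for _, _, c in part.segments)

    def test_segments_tile_domain_exactly(self):
        part = partition_regions(
            [[(3, 9), (15, 20)], [(5, 12)]], [(25, 30)], (0, 40)
        )
        assert part.segments[0][0] == 0 and part.segments[-1][1] == 40
        for (s1, e1, _), (s2, e2, _) in zip(part.segments, part.segments[1:]):
            assert e1 == s2
        assert sum(e - s for s, e, _ in part.segments) == 40

    def test_out_of_domain_interval_rejected(self):
        with pytest.raises(ValueError):
            partition_regions([[(0, 50)]], [], (0, 40))


def dated(start, end, age_ma):
    el = FlLTRElement(chrom="c", ltr5=(start, start + 100), ltr3=(end - 100, end))
    return DatedElement(
        element=el, counts=SubstitutionCounts(100, 0, 0), K=age_ma * 2 * 1.3e-8 * 1e6,
        age_ma=age_ma, incipient=age_ma == 0, valid=True,
    )


class TestRegionAgeSummary:
    def test_young_derived_vs_old_ancestral_ordering(self):
        rng = np.random.default_rng(10)
        part = partition_regions(
            [[(0, 10_000)]] * 3, [(20_000, 30_000)], (0, 40_000)
        )
        els = [dated(int(p), int(p) + 500, a) for p, a in zip(
            rng.integers(0, 9_000, 30), rng.normal(1.2, 0.1, 30)
        )]
        els += [dated(int(p), int(p) + 500, abs(a)) for p, a in zip(
            rng.integers(20_000, 29_000, 30), rng.normal(0.2, 0.05, 30)
        )]
        summaries, tests = region_age_summary(els, part)
        assert summaries["derived_only"].median_ma < summaries["ancestral_all"].median_ma
        row = tests[(tests.class_a == "ancestral_all") & (tests.class_b == "derived_only")]
        assert float(row["p"].iloc[0]) < 0.01

    def test_single_class_only(self):
        part = partition_regions([[(0, 10_000)]] * 3, [], (0, 10_000))
        summaries, tests = region_age_summary([dated(100, 700, 0.5)], part)
        assert list(summaries) == ["ancestral_all"]
        assert tests.empty


class TestCopyTables:
    def test_published_superfamily_percentages(self):
        pct = superfamily_percentages({"Gypsy": 3111, "Copia": 141, "unknown": 344})
        assert pct == {"Gypsy": 86.5, "Copia": 3.9, "unknown": 9.6}
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_counts_assigned_by_midpoint(self):
        assignments = pd.DataFrame(
            [
                {"chrom": "1A", "start": 100, "end": 700, "family_id": "CRW1", "superfamily": "Gypsy"},
                {"chrom": "1A", "start": 5_000, "end": 5_600, "family_id": "CRW1", "superfamily": "Gypsy"},
                {"chrom": "1A", "start": 50_000, "end": 50_600, "family_id": "CRW3", "superfamily": "Gypsy"},
            ]
        )
        calls = [CentromereCall("1A", 0, 10_000)]
        table, pct = crw_copy_table(assignments, calls)
        assert table.loc["CRW1", "1A"] == 2
        assert table.loc["CRW3", "1A"] == 0
        assert pct["Gypsy"] == 100.0

    def test_empty_assignments_give_zero_table(self):
        table, pct = crw_copy_table(
            pd.DataFrame(columns=["chrom", "start", "end", "family_id", "superfamily"]),
            [CentromereCall("1A", 0, 10_000)],
        )
        assert table.empty or (table.to_numpy() == 0).all()
        assert pct == {}
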