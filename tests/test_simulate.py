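"""Synthetic-genome generator: substitution process, planting, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenarch.enrichment import compute_ratio_track
from cenarch.simulate import (
    FamilyConsensus,
    SimulationSpec,
    mutate_sequence,
    plant_element,
    random_family,
    random_sequence,
    simulate_chip,
    simulate_genome,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestMutateSequence:
    def test_zero_rate_is_identity(self):
        seq = "ACGT" * 50
        assert mutate_sequence(seq, 0.0, 2.0, 1) == seq

    def test_changed_fraction_matches_poisson_mean(self):
        # lam = 0.013 per site: P(site changed) ~ 1 - exp(-lam) (back
        # mutation negligible), so ~0.0129 over many replicates
        seq = "ACGT" * 2500
        rng = np.random.default_rng(0)
        changed = 0
        n_rep = 12
        for _ in range(n_rep):
            out = mutate_sequence(seq, 0.013, 2.0, rng)
            changed += sum(1 for a, b in zip(seq, out) if a != b)
        frac = changed / (len(seq) * n_rep)
        assert frac == pytest.approx(0.0129, abs=0.0012)

    def test_large_kappa_gives_pure_transitions(self):
        seq = "A" * 5000
        out = mutate_sequence(seq, 0.01, 1e9, 3)
        assert set(out) <= {"A", "G"}
        assert "G" in out

    def test_non_acgt_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            mutate_sequence("ACNT", 0.1, 2.0, 0)

    @given(seq=dna, lam=st.floats(0, 0.1), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_and_alphabet_preserved(self, seq, lam, seed):
        out = mutate_sequence(seq, lam, 2.0, seed)
        assert len(out) == len(seq)
        assert set(out) <= set("ACGT")


class TestPlantElement:
    @pytest.fixture()
    def fam(self):
        return random_family("F1", np.random.default_rng(5), ltr_len=500, internal_len=3000)

    def test_age_zero_gives_identical_ltr_copies(self, fam):
        seq = random_sequence(20000, np.random.default_rng(1))
        new, rec = plant_element(seq, 8000, fam, 0.0, 1.3e-8, 2.0, 2)
        ltr5 = new[rec.insert_pos : rec.insert_pos + rec.ltr_len]
        ltr3 = new[rec.end - rec.ltr_len : rec.end]
        assert ltr5 == ltr3 == fam.ltr_seq

    def test_tsd_duplicated_on_both_flanks(self, fam):
        seq = random_sequence(20000, np.random.default_rng(1))
        new, rec = plant_element(seq, 8000, fam, 1e6, 1.3e-8, 2.0, 2)
        L = len(rec.tsd)
        assert 4 <= L <= 20
        assert new[rec.insert_pos - L : rec.insert_pos] == rec.tsd
        assert new[rec.end : rec.end + L] == rec.tsd

    def test_expected_divergence_tracks_2rt(self, fam):
        # 1.0 Ma at r = 1.3e-8 -> mean pairwise LTR divergence ~ 0.026
        rng = np.random.default_rng(7)
        seq = random_sequence(10000, rng)
        diffs = []
        for _ in range(50):
            new, rec = plant_element(seq, 5000, fam, 1.0e6, 1.3e-8, 2.0, rng)
            a = new[rec.insert_pos : rec.insert_pos + rec.ltr_len]
            b = new[rec.end - rec.ltr_len : rec.end]
            diffs.append(sum(x != y for x, y in zip(a, b)) / rec.ltr_len)
        assert np.mean(diffs) == pytest.approx(0.026, rel=0.15)

    def test_position_outside_sequence_rejected(self, fam):
        with pytest.raises(ValueError):
            plant_element("ACGT" * 10, 1000, fam, 0.0, 1.3e-8, 2.0, 0)


class TestFamilyConsensus:
    def test_motif_and_size_invariants_enforced(self):
        with pytest.raises(ValueError, match="TG"):
            FamilyConsensus("x", "Gypsy", "AA" + "C" * 200 + "CA", "G" * 3000)
        with pytest.raises(ValueError, match="3000"):
            FamilyConsensus("x", "Gypsy", "TG" + "C" * 100 + "CA", "G" * 100)
        with pytest.raises(ValueError, match="superfamily"):
            FamilyConsensus("x", "Retro", "TG" + "C" * 500 + "CA", "G" * 3000)


class TestSimulateGenome:
    def _spec(self, **kw):
        fams = [random_family("F1", np.random.default_rng(9), ltr_len=500, internal_len=3000)]
        base = dict(
            chrom_length=120_000,
            centromere_interval=(40_000, 80_000),
            n_elements_per_region={"centromeric": 3, "pericentromeric": 1, "arm": 1},
            age_distribution={
                "centromeric": ("point", 0.2),
                "pericentromeric": ("point", 1.0),
                "arm": ("point", 1.0),
            },
            pericentromere_flank=15_000,
            families=fams,
            seed=4,
        )
        base.update(kw)
        return SimulationSpec(**base)

    def test_no_elements_gives_pure_background(self):
        spec = self._spec(n_elements_per_region={}, families=())
        genome, truth = simulate_genome(spec)
        assert len(genome[spec.chrom_name]) == spec.chrom_length
        assert truth.elements == []

    def test_truth_elements_within_bounds_and_tsd_flanked(self):
        genome, truth = simulate_genome(self._spec())
        seq = genome[truth.chrom]
        assert len(truth.elements) == 5
        for el in truth.elements:
            assert 0 <= el.insert_pos < el.end <= len(seq)
            L = len(el.tsd)
            assert seq[el.insert_pos - L : el.insert_pos] == el.tsd
            assert seq[el.end : el.end + L] == el.tsd

    def test_satellite_array_has_requested_size(self):
        spec = self._spec(satellite=(550, 20))
        genome, truth = simulate_genome(spec)
        s, e = truth.satellite_interval
        assert e - s == 550 * 20
        seq = genome[truth.chrom]
        assert seq[s : s + 550] == seq[s + 550 : s + 1100]

    def test_same_seed_reproduces_byte_identical_output(self):
        g1, t1 = simulate_genome(self._spec())
        g2, t2 = simulate_genome(self._spec())
        assert g1 == g2
        assert [e.insert_pos for e in t1.elements] == [e.insert_pos for e in t2.elements]

    def test_centromere_interval_validated(self):
        with pytest.raises(ValueError):
            simulate_genome(self._spec(centromere_interval=(40_000, 200_000)))


class TestSimulateChip:
    def test_null_enrichment_is_indistinguishable(self):
        from scipy import stats

        chip, inp = simulate_chip(10_000_000, (2_000_000, 4_000_000), 1.0, 100.0, 10_000, 5)
        _, p = stats.ks_2samp(chip.values, inp.values)
        assert p > 0.01

    def test_fourfold_centromere_log2_near_two(self):
        # small centromere fraction so CPM scaling is near-neutral
        chip, inp = simulate_chip(200_000_000, (99_000_000, 101_000_000), 4.0, 100.0, 10_000, 6)
        rt = compute_ratio_track(chip, inp)
        bins = slice(9_900, 10_100)
        assert float(np.mean(rt.values[bins])) == pytest.approx(2.0, abs=0.1)

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_chip(1_000_000, (0, 1), 2.0, 10.0, 0, 1)
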