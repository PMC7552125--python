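import math

import numpy as np
import pytest

import strtrace as st
from conftest import (
    pe1p_enumeration,
    pe2p_enumeration,
    pesi_enumeration,
    random_spectrum,
)


class TestMatchingProbability:
    def test_monomorphic_is_certain_match(self):
        assert st.matching_probability({1: 1.0}, "expected") == 1.0

    def test_expected_biallelic_closed_form(self):
        assert st.matching_probability({1: 0.5, 2: 0.5}, "expected") == pytest.approx(0.375)

    def test_expected_near_published_ilst005(self, ilst005_freqs):
        # the published MP (0.463) was computed from observed genotype
        # frequencies; the HWE-expected value from the recovered spectrum
        # lands nearby
        assert st.matching_probability(ilst005_freqs, "expected") == pytest.approx(0.463, abs=0.005)

    def test_observed_counts_genotype_frequencies(self):
        alleles = np.array([[[1, 2]], [[1, 2]], [[1, 1]], [[2, 2]]], dtype=np.int32)
        m = st.GenotypeMatrix(["a", "b", "c", "d"], ["P"] * 4, ["L"], alleles)
        # genotype relative freqs 0.5, 0.25, 0.25
        assert st.matching_probability(m, "observed", "L") == pytest.approx(0.375)


class TestExclusionPowers:
    def test_monomorphic_never_excludes(self):
        assert st.pe_one_parent({1: 1.0}) == 0.0
        assert st.pe_two_parents({1: 1.0}) == 0.0
        assert st.pe_sibling({1: 1.0}) == 0.0

    def test_biallelic_even_closed_forms(self):
        f = {1: 0.5, 2: 0.5}
        assert st.pe_one_parent(f) == pytest.approx(0.125)
        assert st.pe_two_parents(f) == pytest.approx(0.28125)
        assert st.pe_sibling(f) == pytest.approx(0.40625)

    def test_published_ilst005_values(self, ilst005_freqs):
        assert st.pe_one_parent(ilst005_freqs) == pytest.approx(0.069, abs=0.002)
        assert st.pe_two_parents(ilst005_freqs) == pytest.approx(0.237, abs=0.002)
        assert st.pe_sibling(ilst005_freqs) == pytest.approx(0.319, abs=0.002)

    def test_closed_forms_equal_enumeration_on_random_spectra(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):  # a deeper sweep runs in the acceptance suite
            f = random_spectrum(rng, k_max=8)
            assert st.pe_one_parent(f) == pytest.approx(pe1p_enumeration(f), abs=1e-12)
            assert st.pe_two_parents(f) == pytest.approx(pe2p_enumeration(f), abs=1e-12)
            assert st.pe_sibling(f) == pytest.approx(pesi_enumeration(f), abs=1e-12)

    def test_empirical_trio_exclusion_matches_analytic(self):
        """Exclusion rates measured on simulated Mendelian trios reproduce
        the analytic PE-1P and PE-2P within 3 binomial SEs."""
        freqs = {100: 0.4, 102: 0.3, 104: 0.2, 106: 0.1}
        spec = st.AlleleFrequencySpectrum(["L"], {"L": freqs}, {"L": 1000})
        n = 20000
        _, _, off = st.simulate_trios(spec, n, seed=3)
        cand = st.simulate_genotypes(spec, n, seed=4).alleles
        sire = st.simulate_genotypes(spec, n, seed=5).alleles
        dam = st.simulate_genotypes(spec, n, seed=6).alleles

        def carries(g, al):
            return (g[:, :, 0] == al) | (g[:, :, 1] == al)

        a, b = off[:, :, 0], off[:, :, 1]
        lone_excluded = float((~(carries(cand, a) | carries(cand, b))).mean())
        pe1 = st.pe_one_parent(freqs)
        assert abs(lone_excluded - pe1) <= 3 * math.sqrt(pe1 * (1 - pe1) / n)

        compatible = (carries(sire, a) & carries(dam, b)) | (carries(sire, b) & carries(dam, a))
        pair_excluded = float((~compatible).mean())
        pe2 = st.pe_two_parents(freqs)
        assert abs(pair_excluded - pe2) <= 3 * math.sqrt(pe2 * (1 - pe2) / n)

    def test_empirical_sib_mismatch_matches_analytic(self):
        freqs = {100: 0.4, 102: 0.3, 104: 0.2, 106: 0.1}
        spec = st.AlleleFrequencySpectrum(["L"], {"L": freqs}, {"L": 1000})
        n = 20000
        s1, s2 = st.simulate_sib_pairs(spec, n, seed=7)
        mism = float((np.sort(s1, 2) != np.sort(s2, 2)).any(axis=2).mean())
        pesi = st.pe_sibling(freqs)
        assert abs(mism - pesi) <= 3 * math.sqrt(pesi * (1 - pesi) / n)


class TestCombinePanel:
    def test_single_locus_prefix_equals_locus_stats(self, table1):
        curve = st.combine_panel(table1[:1])
        assert curve.cmp[0] == pytest.approx(table1[0].MP, abs=1e-15)
        assert curve.cpe1[0] == pytest.approx(table1[0].PE1P, abs=1e-15)

    def test_published_cpe1_values(self, table1):
        full = st.combine_panel(table1)
        assert round(float(full.cpe1[-1]), 5) == 0.99998
        assert st.combine_panel(table1, st.NAMED_PANELS["stockmarks11"]).cpe1[-1] == pytest.approx(
            0.9911, abs=5e-5
        )
        assert st.combine_panel(table1, st.NAMED_PANELS["isag12"]).cpe1[-1] == pytest.approx(
            0.9946, abs=6e-5
        )

    def test_monotone_trajectories(self, table1):
        curve = st.combine_panel(table1)
        assert (np.diff(curve.cmp) <= 0).all()
        for traj in (curve.cpe1, curve.cpe2, curve.cpesi):
            assert (np.diff(traj) >= 0).all()

    def test_unknown_locus_is_named_in_error(self, table1):
        with pytest.raises(KeyError, match="NOPE"):
            st.combine_panel(table1, ["BM1824", "NOPE"])


class TestMinimalPanelSize:
    def test_zero_threshold_needs_one_locus(self, table1):
        assert st.minimal_panel_size(table1, "PE1P", 0.0).minimal_size == 1

    def test_rank_descending_minimal_sizes(self, table1):
        # cumulative product over the sorted PE columns of the fixture
        assert st.minimal_panel_size(table1, "PE1P", 0.9999).minimal_size == 20
        assert st.minimal_panel_size(table1, "PESI", 0.9999).minimal_size == 10

    def test_unreachable_threshold_reported(self, table1):
        weak = [s for s in table1 if s.locus == "ILST005"]
        design = st.minimal_panel_size(weak, "PE1P", 0.9999)
        assert design.minimal_size is None
        assert design.achieved is None

    def test_adding_a_locus_never_hurts(self, table1):
        """Monotone panel property on every prefix of the fixture order."""
        curve = st.combine_panel(table1)
        for i in range(1, len(table1)):
            assert curve.cpe1[i] >= curve.cpe1[i - 1]
            assert curve.cmp[i] <= curve.cmp[i - 1]
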