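import math

import numpy as np
import pytest

import strtrace as st


def _spectrum(freqs_by_locus, n=100, counts=None):
    loci = list(freqs_by_locus)
    return st.AlleleFrequencySpectrum(
        loci, freqs_by_locus, {l: n for l in loci}, counts or {}
    )


class TestGenotypeLogScore:
    def test_frequency_method_hwe_likelihood(self):
        ref = _spectrum({"L": {1: 0.5, 2: 0.5}})
        score = st.genotype_log_score({"L": (1, 2)}, ref, "frequency")
        assert score == pytest.approx(math.log(0.5))

    def test_zero_frequency_substitution_keeps_score_finite(self):
        ref = _spectrum({"L": {1: 0.9, 2: 0.1}})
        score = st.genotype_log_score({"L": (7, 7)}, ref, "frequency", zero_freq=0.01)
        assert score == pytest.approx(math.log(0.01 * 0.01))

    def test_bayesian_converges_to_frequency_score(self):
        f = {1: 0.6, 2: 0.4}
        for big_n in (10**4, 10**6):
            counts = {"L": {1: int(2 * big_n * 0.6), 2: int(2 * big_n * 0.4)}}
            ref = _spectrum({"L": f}, n=big_n, counts=counts)
            bay = st.genotype_log_score({"L": (1, 2)}, ref, "bayesian")
            freq = st.genotype_log_score({"L": (1, 2)}, ref, "frequency")
            assert bay == pytest.approx(freq, abs=10.0 / big_n)

    def test_missing_loci_skipped_and_empty_rejected(self):
        ref = _spectrum({"L1": {1: 0.5, 2: 0.5}, "L2": {1: 1.0}})
        s = st.genotype_log_score({"L1": (1, 1), "L2": None}, ref)
        assert s == pytest.approx(math.log(0.25))
        with pytest.raises(ValueError):
            st.genotype_log_score({"L1": None}, ref)


class TestSelfAssign:
    def test_private_allele_pulls_assignment_home(self):
        alleles = np.array(
            [[[1, 1]], [[1, 1]], [[1, 9]], [[2, 2]], [[2, 2]], [[2, 2]]],
            dtype=np.int32,
        )
        m = st.GenotypeMatrix(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            ["A"] * 3 + ["B"] * 3,
            ["L"],
            alleles,
        )
        res = st.self_assign(m)
        assert res.assigned["a3"] == "A"

    def test_tie_broken_by_first_label_and_flagged(self):
        alleles = np.array([[[1, 2]]] * 4, dtype=np.int32)
        m = st.GenotypeMatrix(
            ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"], ["L"], alleles
        )
        res = st.self_assign(m)
        assert (res.assigned == "A").all()
        assert res.ambiguous.all()

    def test_leave_one_out_excludes_own_alleles(self):
        """An individual whose allele is unique in its population must not
        profit from its own copies: with leave-one-out its home score uses
        the zero-frequency substitute."""
        alleles = np.array(
            [[[9, 9]], [[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], dtype=np.int32
        )
        m = st.GenotypeMatrix(
            ["a1", "a2", "a3", "b1", "b2"], ["A"] * 3 + ["B"] * 2, ["L"], alleles
        )
        res = st.self_assign(m, zero_freq=0.01)
        assert res.scores.loc["a1", "A"] == pytest.approx(math.log(0.01**2))

    def test_simulated_breeds_assign_home(self):
        spec = st.PopulationSpec(n_populations=3, fst=0.12, n_loci=30, sizes=(40, 40, 40), seed=17)
        m = st.simulate_dataset(spec)
        res = st.self_assign(m)
        accuracy = float((res.assigned.values == np.array(m.pops)).mean())
        assert accuracy >= 0.95


class TestExclusionTest:
    def test_minimal_p_for_impossible_genotype(self):
        ref = _spectrum({"L": {1: 0.999999, 2: 1e-6}})
        p = st.exclusion_test({"L": (3, 3)}, ref, n_sim=1000, seed=0, zero_freq=1e-12)
        assert p == pytest.approx(1 / 1001)

    def test_p_monotone_in_score_rank(self):
        ref = _spectrum({"L": {1: 0.7, 2: 0.2, 3: 0.1}})
        common = st.exclusion_test({"L": (1, 1)}, ref, n_sim=2000, seed=5)
        rare = st.exclusion_test({"L": (3, 3)}, ref, n_sim=2000, seed=5)
        assert rare <= common

    def test_type_one_error_calibration(self):
        """Individuals drawn from the reference itself are excluded at no
        more than twice the nominal 0.001 rate."""
        spec = st.PopulationSpec(n_populations=1, fst=0.0, n_loci=10, sizes=(50,), seed=42)
        freqs = st.simulate_frequencies(spec)[0]
        rng = np.random.default_rng(0)
        n_reps = 2000
        exclusions = 0
        for _ in range(n_reps):
            ind_m = st.simulate_genotypes(freqs, 1, rng=rng)
            ind = {l: ind_m.genotype(0, l) for l in freqs.loci}
            p = st.exclusion_test(ind, freqs, 1000, seed=int(rng.integers(2**31)))
            exclusions += p <= 0.001
        assert exclusions / n_reps <= 2 * 0.001

    def test_reproducible_given_seed(self):
        ref = _spectrum({"L": {1: 0.7, 2: 0.3}})
        a = st.exclusion_test({"L": (2, 2)}, ref, seed=9)
        b = st.exclusion_test({"L": (2, 2)}, ref, seed=9)
        assert a == b


class TestCrossValidate:
    def test_undifferentiated_pair_assigns_at_chance(self):
        spec = st.PopulationSpec(n_populations=2, fst=0.0, n_loci=10, sizes=(40, 40), seed=5)
        m = st.simulate_dataset(spec)
        report = st.cross_validate(m, [20], [10], iterations=20, seed=1)
        overall = float(report.table["mean"].mean())
        # 3 SEs around 0.5 given 20 held-out individuals x 20 iterations
        assert abs(overall - 0.5) <= 3 * math.sqrt(0.25 / (20 * 20)) + 0.05

    def test_fixed_differences_assign_perfectly(self):
        alleles = np.zeros((40, 5, 2), dtype=np.int32)
        alleles[:20] = 100
        alleles[20:] = 120
        m = st.GenotypeMatrix(
            [f"i{k}" for k in range(40)],
            ["A"] * 20 + ["B"] * 20,
            [f"L{j}" for j in range(5)],
            alleles,
        )
        report = st.cross_validate(m, [10], [5], iterations=5, seed=3)
        assert report.table["mean"].min() == 1.0

    def test_accuracy_non_decreasing_in_locus_count(self):
        spec = st.PopulationSpec(n_populations=2, fst=0.12, n_loci=30, sizes=(40, 40), seed=6)
        m = st.simulate_dataset(spec)
        report = st.cross_validate(m, [20], [5, 15, 30], iterations=20, seed=2)
        means = report.table.groupby("n_loci")["mean"].mean()
        assert means[15] >= means[5] - 0.05
        assert means[30] >= means[15] - 0.05

    def test_infeasible_training_size_names_population(self):
        spec = st.PopulationSpec(n_populations=2, fst=0.1, n_loci=5, sizes=(10, 30), seed=8)
        m = st.simulate_dataset(spec)
        with pytest.raises(ValueError, match="pop1"):
            st.cross_validate(m, [10], [5], iterations=2, seed=1)

    def test_bit_for_bit_reproducible(self):
        spec = st.PopulationSpec(n_populations=2, fst=0.15, n_loci=8, sizes=(20, 20), seed=12)
        m = st.simulate_dataset(spec)
        r1 = st.cross_validate(m, [10], [4, 8], iterations=5, seed=77)
        r2 = st.cross_validate(m, [10], [4, 8], iterations=5, seed=77)
        assert r1.table.equals(r2.table)
        assert r1.cell(10, 8, "pop1")[0] == r2.cell(10, 8, "pop1")[0]
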