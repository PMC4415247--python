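import math

import numpy as np
import pytest

from immunopop import differentiation as diff
from immunopop.model import DistanceMatrixLabeled, GenotypeRecord, PopulationGenotypes


class TestDiversityComponents:
    def test_fixed_for_different_alleles(self):
        comp = diff.diversity_components([{"a": 10}, {"b": 10}], "naive")
        assert comp.H_S == pytest.approx(0.0)
        assert comp.H_T == pytest.approx(0.5)

    def test_hand_computed_naive(self):
        comp = diff.diversity_components([{"a": 7, "b": 3}, {"a": 3, "b": 7}], "naive")
        assert comp.H_S == pytest.approx(0.42)
        assert comp.H_T == pytest.approx(0.5)

    def test_identical_frequencies(self):
        comp = diff.diversity_components([{"a": 6, "b": 4}, {"a": 3, "b": 2}], "naive")
        assert comp.H_S == pytest.approx(comp.H_T)

    def test_bias_corrected_formulas(self):
        counts = [{"a": 7, "b": 3}, {"a": 3, "b": 7}]
        naive = diff.diversity_components(counts, "naive")
        corr = diff.diversity_components(counts, "bias_corrected")
        n_harm = 2 / (1 / 5 + 1 / 5)
        assert corr.N_harmonic == pytest.approx(n_harm)
        assert corr.H_S == pytest.approx(naive.H_S * n_harm / (n_harm - 1))
        assert corr.H_T == pytest.approx(naive.H_T + corr.H_S / (2 * n_harm * 2))


class TestEstimators:
    def test_jost_d_hand_value(self):
        comp = diff.diversity_components([{"a": 7, "b": 3}, {"a": 3, "b": 7}], "naive")
        assert diff.jost_d(comp) == pytest.approx(0.2759, abs=5e-5)

    def test_gst_prime_hand_value(self):
        comp = diff.diversity_components([{"a": 7, "b": 3}, {"a": 3, "b": 7}], "naive")
        assert diff.hedrick_gst_prime(comp) == pytest.approx(0.3917, abs=5e-5)

    def test_fixed_pair_gives_unity(self):
        comp = diff.diversity_components([{"a": 10}, {"b": 10}], "naive")
        assert diff.jost_d(comp) == pytest.approx(1.0)
        assert diff.hedrick_gst_prime(comp) == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        comp = diff.diversity_components([{"a": 6, "b": 4}, {"a": 6, "b": 4}], "naive")
        assert diff.jost_d(comp) == pytest.approx(0.0, abs=1e-12)
        assert diff.hedrick_gst_prime(comp) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_pools_unity_over_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k1, k2 = rng.integers(1, 6, size=2)
            c1 = {f"x{i}": int(rng.integers(1, 30)) for i in range(k1)}
            c2 = {f"y{i}": int(rng.integers(1, 30)) for i in range(k2)}
            comp = diff.diversity_components([c1, c2], "naive")
            assert diff.jost_d(comp) == pytest.approx(1.0)

    def test_gst_prime_at_least_gst(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            c1 = {f"a{i}": int(rng.integers(1, 20)) for i in range(3)}
            c2 = {f"a{i}": int(rng.integers(1, 20)) for i in range(3)}
            comp = diff.diversity_components([c1, c2], "naive")
            g = diff.gst(comp)
            if not math.isnan(g):
                assert diff.hedrick_gst_prime(comp) >= g - 1e-12


def _two_pop_genotypes(locus_alleles):
    """locus -> ((pop1 allele pairs), (pop2 allele pairs))."""
    records = []
    for locus, (pairs1, pairs2) in locus_alleles.items():
        for pop, pairs in (("P1", pairs1), ("P2", pairs2)):
            for i, (a, b) in enumerate(pairs):
                records.append(GenotypeRecord(f"{pop}_{locus}_{i}", pop, locus, a, b))
    return PopulationGenotypes(records, populations=["P1", "P2"])


class TestPairwiseDifferentiation:
    def test_mean_across_loci(self):
        genotypes = _two_pop_genotypes(
            {
                "L1": ([("a", "a")] * 5, [("b", "b")] * 5),  # disjoint: D = 1
                "L2": ([("c", "d")] * 5, [("c", "d")] * 5),  # identical: D = 0
            }
        )
        m = diff.pairwise_differentiation(
            genotypes, ["L1", "L2"], statistic="d", estimator="naive"
        )
        assert m.get("P1", "P2") == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self):
        genotypes = _two_pop_genotypes(
            {"L1": ([("a", "b")] * 4, [("b", "c")] * 6)}
        )
        m = diff.pairwise_differentiation(genotypes, ["L1"], estimator="naive")
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_population_order_invariance(self):
        records = []
        pools = {"A": ["x", "y"], "B": ["y", "z"], "C": ["w", "w"]}
        for pop, (a1, a2) in pools.items():
            for i in range(6):
                records.append(GenotypeRecord(f"{pop}{i}", pop, "L", a1 if i % 2 else a2, a1))
        g1 = PopulationGenotypes(records, populations=["A", "B", "C"])
        g2 = PopulationGenotypes(records, populations=["C", "A", "B"])
        m1 = diff.pairwise_differentiation(g1, ["L"], estimator="naive")
        m2 = diff.pairwise_differentiation(g2, ["L"], estimator="naive")
        assert m1.get("A", "B") == pytest.approx(m2.get("A", "B"))
        assert m1.get("B", "C") == pytest.approx(m2.get("B", "C"))

    def test_identity_supertype_mapping_equals_allele_level(self):
        genotypes = _two_pop_genotypes(
            {"L1": ([("a", "b"), ("a", "a"), ("b", "c")], [("c", "c"), ("b", "c"), ("a", "c")])}
        )
        identity = {a: a for a in "abc"}
        direct = diff.pairwise_differentiation(genotypes, ["L1"], estimator="naive")
        mapped = diff.pairwise_differentiation(
            genotypes, ["L1"], estimator="naive", allele_mapping=identity
        )
        assert np.allclose(direct.values, mapped.values)

    def test_shared_rare_allele_below_unity(self):
        genotypes = _two_pop_genotypes(
            {"L1": ([("a", "a")] * 9 + [("s", "s")], [("b", "b")] * 9 + [("s", "s")])}
        )
        m = diff.pairwise_differentiation(genotypes, ["L1"], statistic="d", estimator="naive")
        # oracle: direct evaluation of the naive formulas
        comp = diff.diversity_components(
            [{"a": 18, "s": 2}, {"b": 18, "s": 2}], "naive"
        )
        assert m.get("P1", "P2") == pytest.approx(diff.jost_d(comp))
        assert m.get("P1", "P2") < 1.0


class TestMantel:
    def _random_distance(self, rng, labels):
        n = len(labels)
        x = rng.random((n, 2))
        values = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        return DistanceMatrixLabeled(labels, values)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m = self._random_distance(rng, list("abcde"))
        r, p = diff.mantel_test(m, m, reps=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_r_equals_direct_pearson(self):
        rng = np.random.default_rng(1)
        labels = list("abcdef")
        m1 = self._random_distance(rng, labels)
        m2 = self._random_distance(rng, labels)
        r, _ = diff.mantel_test(m1, m2, reps=99, seed=0)
        iu = np.triu_indices(len(labels), k=1)
        assert r == pytest.approx(np.corrcoef(m1.values[iu], m2.values[iu])[0, 1])

    def test_agrees_with_skbio_oracle(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(2)
        labels = [f"p{i}" for i in range(7)]
        m1 = self._random_distance(rng, labels)
        m2 = self._random_distance(rng, labels)
        r_ours, _ = diff.mantel_test(m1, m2, reps=99, seed=0)
        r_skbio, _, _ = mantel(
            DistanceMatrix(m1.values, labels),
            DistanceMatrix(m2.values, labels),
            permutations=0,
        )
        assert r_ours == pytest.approx(float(r_skbio))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        labels = [f"p{i}" for i in range(8)]
        ps = []
        for i in range(100):
            m1 = self._random_distance(rng, labels)
            m2 = self._random_distance(rng, labels)
            _, p = diff.mantel_test(m1, m2, reps=199, seed=i)
            ps.append(p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_undefined(self):
        labels = list("abc")
        const = DistanceMatrixLabeled(labels, np.ones((3, 3)) - np.eye(3))
        varying = DistanceMatrixLabeled(
            labels, np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        )
        with pytest.raises(ValueError):
            diff.mantel_test(varying, const, reps=99)


class TestGeography:
    def test_great_circle_known_value(self):
        # one degree of latitude is ~111 km
        d = diff.great_circle_km(-37.0, 175.0, -38.0, 175.0)
        assert d == pytest.approx(111.2, rel=0.01)

    def test_matrix_symmetry(self):
        coords = {"a": (-37.0, 175.0), "b": (-38.0, 176.0), "c": (-36.5, 177.0)}
        m = diff.geographic_distance_matrix(coords)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
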