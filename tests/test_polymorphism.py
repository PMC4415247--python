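import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from immunopop import polymorphism as poly
from immunopop.model import AlleleCatalog


class TestHeterozygosity:
    def test_observed_fraction(self, otawa_genotypes):
        h_o = poly.observed_heterozygosity(otawa_genotypes, "Otawa", "DAB")
        assert h_o == pytest.approx(2 / 19)

    @pytest.mark.parametrize(
        "counts,expected",
        [({"a": 36, "b": 2}, 0.100), ({"a": 10}, 0.0), ({"a": 5, "b": 5}, 0.5)],
    )
    def test_expected_uncorrected(self, counts, expected):
        assert poly.expected_heterozygosity(counts) == pytest.approx(expected, abs=5e-4)

    def test_unbiased_factor(self):
        counts = {"a": 36, "b": 2}
        biased = poly.expected_heterozygosity(counts)
        unbiased = poly.expected_heterozygosity(counts, unbiased=True)
        assert unbiased == pytest.approx(biased * 38 / 37)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"a": 36, "b": 2}, 0.102),
            ({chr(97 + i): 1 for i in range(6)}, 1.0),
            ({"a": 9}, 0.0),
        ],
    )
    def test_haplotype_diversity(self, counts, expected):
        if sum(counts.values()) < 2:
            with pytest.raises(ValueError):
                poly.haplotype_diversity(counts)
        else:
            assert poly.haplotype_diversity(counts) == pytest.approx(expected, abs=5e-4)

    @given(
        hst.lists(hst.integers(min_value=1, max_value=30), min_size=1, max_size=6)
    )
    def test_uncorrected_he_below_hd(self, counts):
        if sum(counts) < 2:
            return
        h_e = poly.expected_heterozygosity(counts)
        hd = poly.haplotype_diversity(counts)
        assert h_e <= hd + 1e-12


class TestPairwiseDiffStats:
    def test_two_allele_weighted(self, otawa_catalog):
        s, k, pi = poly.pairwise_diff_stats(otawa_catalog, {"DAB*74": 36, "DAB*73": 2})
        assert s == 23
        assert k == pytest.approx(23 * 36 * 2 / math.comb(38, 2))
        assert round(k, 2) == 2.36
        assert round(pi, 4) == 0.0108

    def test_identical_copies(self, otawa_catalog):
        s, k, pi = poly.pairwise_diff_stats(otawa_catalog, {"DAB*74": 10})
        assert (s, k, pi) == (0, 0.0, 0.0)

    def test_three_singletons_brute_force(self):
        catalog = AlleleCatalog("L", {"x": "AAA", "y": "AAT", "z": "ATT"})
        s, k, pi = poly.pairwise_diff_stats(catalog, {"x": 1, "y": 1, "z": 1})
        assert s == 2
        assert k == pytest.approx(4 / 3)  # (1 + 2 + 1) / 3 pairs
        assert pi * 3 == pytest.approx(k)

    def test_pi_times_length_equals_k(self, otawa_catalog):
        _, k, pi = poly.pairwise_diff_stats(otawa_catalog, {"DAB*74": 3, "DAB*73": 5})
        assert pi * otawa_catalog.alignment_length == pytest.approx(k)


def exhaustive_rarefaction(counts, g):
    """Oracle: mean distinct alleles over all gene-copy subsets of size g."""
    pool = [a for a, c in counts.items() for _ in range(c)]
    subsets = list(itertools.combinations(range(len(pool)), g))
    return np.mean([len({pool[i] for i in s}) for s in subsets])


class TestRarefaction:
    def test_full_sample_returns_allele_count(self):
        counts = {"a": 4, "b": 2, "c": 1}
        assert poly.allelic_richness_rarefaction(counts, 7) == pytest.approx(3.0)

    def test_enumeration_example(self):
        assert poly.allelic_richness_rarefaction({"a": 3, "b": 1}, 2) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "counts", [{"a": 3, "b": 1}, {"a": 2, "b": 2, "c": 2}, {"a": 5, "b": 3}]
    )
    def test_matches_exhaustive_enumeration(self, counts):
        total = sum(counts.values())
        for g in range(1, total + 1):
            assert poly.allelic_richness_rarefaction(counts, g) == pytest.approx(
                exhaustive_rarefaction(counts, g)
            )

    def test_nondecreasing_in_g(self):
        counts = {"a": 10, "b": 5, "c": 2, "d": 1}
        values = [poly.allelic_richness_rarefaction(counts, g) for g in range(1, 19)]
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(values, values[1:]))

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            poly.allelic_richness_rarefaction({"a": 3}, 0)
        with pytest.raises(ValueError):
            poly.allelic_richness_rarefaction({"a": 3}, 4)


class TestAlleleCountCI:
    def test_single_allele_pool(self):
        assert poly.allele_count_ci_permutation({"a": 100}, 5, reps=200, seed=0) == (1, 1)

    def test_all_distinct_pool(self):
        pool = {f"a{i}": 1 for i in range(100)}
        assert poly.allele_count_ci_permutation(pool, 5, reps=200, seed=0) == (10, 10)

    def test_deterministic_given_seed(self):
        pool = {f"a{i}": c for i, c in enumerate([30, 20, 10, 5, 3, 2, 1, 1])}
        a = poly.allele_count_ci_permutation(pool, 10, reps=500, seed=7)
        b = poly.allele_count_ci_permutation(pool, 10, reps=500, seed=7)
        assert a == b

    def test_warns_on_few_reps(self):
        with pytest.warns(UserWarning):
            poly.allele_count_ci_permutation({"a": 5, "b": 5}, 2, reps=50, seed=0)


class TestHWEExact:
    def test_levene_enumeration_small_case(self):
        # allele counts {4,2}: configurations have probabilities 0.8 / 0.2
        two_het = [("a", "a"), ("a", "b"), ("a", "b")]
        zero_het = [("a", "a"), ("a", "a"), ("b", "b")]
        assert poly.hwe_exact_test(two_het) == pytest.approx(1.0)
        assert poly.hwe_exact_test(zero_het) == pytest.approx(0.2)
        assert poly.hwe_exact_test(zero_het, alternative="het_deficit") == pytest.approx(0.2)

    def test_monomorphic(self):
        assert poly.hwe_exact_test([("a", "a")] * 5) == 1.0

    def test_enumeration_matches_monte_carlo(self):
        pairs = [("a", "a")] * 3 + [("a", "b")] * 2 + [("b", "b")] * 2
        exact = poly.hwe_exact_test(pairs)
        mc = poly.hwe_exact_test(pairs, max_configurations=0, reps=4000, seed=5)
        se = math.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc - exact) < max(3 * se, 0.02)

    def test_het_deficit_direction(self):
        # strong homozygote excess should give a small het-deficit p
        pairs = [("a", "a")] * 10 + [("b", "b")] * 10
        p = poly.hwe_exact_test(pairs, alternative="het_deficit")
        assert p < 0.001


class TestGenotypicLD:
    def test_perfect_association(self):
        rng = np.random.default_rng(0)
        genos = []
        for _ in range(20):
            g = tuple(sorted(rng.choice(["a", "b"], size=2)))
            genos.append((g, g))  # locus B mirrors locus A
        p = poly.genotypic_ld_test(genos, reps=999, seed=1)
        assert p <= 0.01

    def test_monomorphic_locus(self):
        genos = [(("a", "a"), ("x", "x"))] * 10
        assert poly.genotypic_ld_test(genos) == 1.0

    def test_independent_loci_not_extreme(self):
        rng = np.random.default_rng(3)
        genos = [
            (
                tuple(sorted(rng.choice(["a", "b"], size=2))),
                tuple(sorted(rng.choice(["x", "y"], size=2))),
            )
            for _ in range(40)
        ]
        p = poly.genotypic_ld_test(genos, reps=499, seed=2)
        assert p > 0.01


class TestHolmBonferroni:
    def test_step_down_example(self):
        assert poly.holm_bonferroni([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        assert poly.holm_bonferroni([0.2]) == [pytest.approx(0.2)]
        assert poly.holm_bonferroni([1.0, 1.0]) == [1.0, 1.0]

    @given(
        hst.lists(
            hst.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        adj = poly.holm_bonferroni(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        order = np.argsort(ps, kind="stable")
        sorted_adj = np.array(adj)[order]
        assert all(b >= a - 1e-12 for a, b in zip(sorted_adj, sorted_adj[1:]))


class TestRichnessRegression:
    def test_identity(self):
        fit = poly.richness_regression([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        fit = poly.richness_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            poly.richness_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
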