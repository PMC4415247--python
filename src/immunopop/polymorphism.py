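"""Per-population diversity statistics for sequence and genotype data.

Implements the classic polymorphism summaries for a locus within each
population: observed/expected heterozygosity, haplotype (gene) diversity,
segregating sites, mean pairwise nucleotide differences (k) and nucleotide
diversity (pi), hypergeometric rarefaction allelic richness, a permutation
confidence interval for the expected allele count at a given sample size,
exact Hardy–Weinberg tests on the Levene conditional distribution, a
permutation G-test of genotypic linkage disequilibrium, Holm–Bonferroni
correction, and the richness-on-richness regression used to gauge drift.

Conventions chosen to match the two program lineages these statistics come
from: expected heterozygosity is the uncorrected 1 - sum(p^2) (GenAlEx
style) unless ``unbiased=True``, while haplotype diversity always carries
the n/(n-1) small-sample factor (DnaSP style).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .model import AlleleCatalog, PopulationGenotypes

__all__ = [
    "PolymorphismSummary",
    "RegressionResult",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "haplotype_diversity",
    "pairwise_diff_stats",
    "allelic_richness_rarefaction",
    "allele_count_ci_permutation",
    "hwe_exact_test",
    "genotypic_ld_test",
    "holm_bonferroni",
    "richness_regression",
    "population_summary",
]


@dataclass
class PolymorphismSummary:
    population: str
    N: int
    A: float
    A_R: float
    ci_NA: tuple[int, int] | None
    H_O: float
    H_E: float
    Hd: float | None
    S: int | None
    pi: float | None
    k: float | None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    n: int


def _frequencies(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts),
        dtype=float,
    )
    values = values[values > 0]
    total = values.sum()
    if total <= 0:
        raise ValueError("no allele copies")
    return values / total


def observed_heterozygosity(
    genotypes: PopulationGenotypes, population: str, locus: str
) -> float:
    """Fraction of typed diploid samples that are heterozygous."""
    typed = genotypes.typed(population, locus)
    if not typed:
        raise ValueError(f"no typed samples for {population}/{locus}")
    return sum(r.is_heterozygous for r in typed) / len(typed)


def expected_heterozygosity(
    counts: Mapping[str, int] | Sequence[int], unbiased: bool = False
) -> float:
    """Gene diversity 1 - sum(p_i^2); ``unbiased`` applies 2N/(2N-1)."""
    if isinstance(counts, Mapping):
        total = sum(counts.values())
    else:
        total = sum(counts)
    if total < 2:
        raise ValueError("need at least two gene copies")
    p = _frequencies(counts)
    h = 1.0 - float(np.sum(p**2))
    if unbiased:
        h *= total / (total - 1)
    return h


def haplotype_diversity(counts: Mapping[str, int] | Sequence[int]) -> float:
    """(n/(n-1)) * (1 - sum p_i^2), the sample-corrected gene diversity."""
    return expected_heterozygosity(counts, unbiased=True)


def _usable_columns(seqs: list[str], max_gap_fraction: float = 0.5) -> np.ndarray:
    """Columns where at most half of the present alleles carry a gap."""
    arr = np.array([list(s) for s in seqs])
    gap_frac = (arr == "-").mean(axis=0)
    return gap_frac <= max_gap_fraction


def pairwise_diff_stats(
    catalog: AlleleCatalog, counts: Mapping[str, int]
) -> tuple[int, float, float]:
    """Segregating sites S, mean pairwise differences k, and pi = k/L.

    ``counts`` gives gene-copy counts per allele id; pairs are weighted by
    copy number over all C(n,2) copy pairs.  Gap handling is pairwise
    deletion — a column with a gap or N in either member of a pair is skipped
    for that pair — and L is the number of columns with <= 50% gaps among the
    alleles present.
    """
    present = [a for a, c in counts.items() if c > 0]
    n = sum(counts[a] for a in present)
    if n < 2:
        raise ValueError("need at least two gene copies")
    seqs = [catalog.sequence(a) for a in present]
    arr = np.array([list(s) for s in seqs])
    copy_n = np.array([counts[a] for a in present], dtype=float)

    observed = (arr != "-") & (arr != "N")
    # S: columns with >=2 distinct observed states among present alleles
    s_count = 0
    for col in range(arr.shape[1]):
        states = set(arr[observed[:, col], col])
        if len(states) >= 2:
            s_count += 1

    total_diffs = 0.0
    for i, j in itertools.combinations(range(len(present)), 2):
        both = observed[i] & observed[j]
        d_ij = int(np.sum((arr[i] != arr[j]) & both))
        total_diffs += d_ij * copy_n[i] * copy_n[j]
    n_pairs = n * (n - 1) / 2
    k = total_diffs / n_pairs

    l_used = int(np.sum(_usable_columns(seqs)))
    if l_used == 0:
        raise ValueError("no usable alignment columns")
    pi = k / l_used
    return s_count, k, pi


def allelic_richness_rarefaction(
    counts: Mapping[str, int] | Sequence[int], g: int
) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    Hypergeometric rarefaction: sum_i [1 - C(N-N_i, g) / C(N, g)].
    """
    if g < 1:
        raise ValueError("subsample size g must be >= 1")
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts),
        dtype=int,
    )
    values = values[values > 0]
    total = int(values.sum())
    if g > total:
        raise ValueError(f"g={g} exceeds total gene copies {total}")

    def log_comb(n: int, r: int) -> float:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    richness = 0.0
    for n_i in values:
        if total - n_i < g:
            richness += 1.0
        else:
            richness += 1.0 - math.exp(log_comb(total - n_i, g) - log_comb(total, g))
    return richness


def multilocus_richness(
    per_locus_counts: Iterable[Mapping[str, int]], g: int
) -> float:
    """Mean rarefied richness across loci at common subsample size g."""
    values = [allelic_richness_rarefaction(c, g) for c in per_locus_counts]
    return float(np.mean(values))


def allele_count_ci_permutation(
    pooled_counts: Mapping[str, int],
    n_pop: int,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[int, int]:
    """95% CI for the number of distinct alleles expected at sample size n_pop.

    Draws ``reps`` subsamples of 2*n_pop gene copies without replacement from
    the pooled copy multiset and returns the 2.5th/97.5th percentiles of the
    distinct-allele count.
    """
    if reps < 100:
        warnings.warn("fewer than 100 permutation replicates; CI will be coarse")
    draw = 2 * n_pop
    pool = np.repeat(
        np.arange(len(pooled_counts)), np.fromiter(pooled_counts.values(), dtype=int)
    )
    if draw > pool.size:
        raise ValueError("requested subsample exceeds pooled copies")
    rng = np.random.default_rng(seed)
    n_distinct = np.empty(reps, dtype=int)
    for r in range(reps):
        sample = rng.choice(pool, size=draw, replace=False)
        n_distinct[r] = np.unique(sample).size
    low, high = np.percentile(n_distinct, [2.5, 97.5])
    return int(low), int(high)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test on the Levene conditional distribution
# ---------------------------------------------------------------------------


def _config_log_prob(config: Mapping[tuple[int, int], int], allele_counts: Sequence[int]) -> float:
    n_ind = sum(config.values())
    n_copies = sum(allele_counts)
    het = sum(v for (i, j), v in config.items() if i != j)
    logp = (
        gammaln(n_ind + 1)
        + sum(gammaln(c + 1) for c in allele_counts)
        + het * math.log(2)
        - gammaln(n_copies + 1)
        - sum(gammaln(v + 1) for v in config.values())
    )
    return logp


def _enumerate_configs(allele_counts: Sequence[int], limit: int):
    """Yield all genotype-count tables with the given allele-copy margins."""
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    counts = list(allele_counts)
    config: dict[tuple[int, int], int] = {}
    visited = 0

    def rec(idx: int):
        nonlocal visited
        if idx == len(pairs):
            if all(c == 0 for c in counts):
                yield dict(config)
            return
        i, j = pairs[idx]
        if i == j:
            max_n = counts[i] // 2
        else:
            max_n = min(counts[i], counts[j])
        # remaining pairs involving allele i after idx
        for n_ij in range(max_n, -1, -1):
            visited += 1
            if visited > limit:
                raise _EnumerationTooLarge
            use = 2 * n_ij if i == j else n_ij
            counts[i] -= use if i == j else n_ij
            if i != j:
                counts[j] -= n_ij
            config[(i, j)] = n_ij
            # prune: allele i must be exhausted once all its pairs are placed
            last_pair_of_i = j == k - 1
            if not (last_pair_of_i and counts[i] != 0):
                yield from rec(idx + 1)
            del config[(i, j)]
            counts[i] += use if i == j else n_ij
            if i != j:
                counts[j] += n_ij

    yield from rec(0)


class _EnumerationTooLarge(Exception):
    pass


def hwe_exact_test(
    genotype_pairs: Sequence[tuple[str, str]],
    alternative: str = "global",
    max_configurations: int = 1_000_000,
    reps: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Exact Hardy–Weinberg test conditional on the observed allele counts.

    ``genotype_pairs`` are (allele, allele) tuples for typed samples at one
    population/locus.  Under the Levene distribution, ``global`` sums the
    probabilities of all genotype configurations no more probable than the
    observed one; ``het_deficit`` sums configurations with at most the
    observed number of heterozygotes.  Enumeration is exhaustive while the
    visited configuration space stays within ``max_configurations``;
    otherwise the null is sampled by ``reps`` random pairings of the
    gene-copy multiset (an exact i.i.d. sampler for the same distribution).
    """
    if alternative not in {"global", "het_deficit"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(genotype_pairs) < 2:
        raise ValueError("need at least two typed samples")
    alleles = sorted({a for pair in genotype_pairs for a in pair})
    if len(alleles) == 1:
        return 1.0
    index = {a: i for i, a in enumerate(alleles)}
    allele_counts = [0] * len(alleles)
    obs_config: Counter = Counter()
    for a, b in genotype_pairs:
        i, j = sorted((index[a], index[b]))
        obs_config[(i, j)] += 1
        allele_counts[i] += 1
        allele_counts[j] += 1

    obs_logp = _config_log_prob(obs_config, allele_counts)
    obs_het = sum(v for (i, j), v in obs_config.items() if i != j)
    tol = 1e-9

    try:
        if len(alleles) > 10:
            # configuration space certainly exceeds any practical limit
            raise _EnumerationTooLarge
        p_total = 0.0
        for config in _enumerate_configs(allele_counts, max_configurations):
            logp = _config_log_prob(config, allele_counts)
            if alternative == "global":
                if logp <= obs_logp + tol:
                    p_total += math.exp(logp)
            else:
                het = sum(v for (i, j), v in config.items() if i != j)
                if het <= obs_het:
                    p_total += math.exp(logp)
        return min(1.0, p_total)
    except _EnumerationTooLarge:
        pass

    # Monte-Carlo: shuffle gene copies, pair consecutively — an exact i.i.d.
    # draw from the Levene conditional distribution.
    rng = np.random.default_rng(seed)
    k = len(alleles)
    copies = np.repeat(np.arange(k), allele_counts)
    n_ind = copies.size // 2
    const = (
        gammaln(n_ind + 1)
        + sum(gammaln(c + 1) for c in allele_counts)
        - gammaln(copies.size + 1)
    )
    lgamma_cache = gammaln(np.arange(n_ind + 2))
    hits = 0
    for _ in range(reps):
        rng.shuffle(copies)
        a = copies[0::2]
        b = copies[1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        het = int(np.sum(lo != hi))
        if alternative == "het_deficit":
            if het <= obs_het:
                hits += 1
            continue
        pair_counts = np.bincount(lo * k + hi, minlength=k * k)
        logp = const + het * math.log(2) - float(
            np.sum(lgamma_cache[pair_counts[pair_counts > 0] + 1])
        )
        if logp <= obs_logp + tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def genotypic_ld_test(
    genotype_pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    reps: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Permutation G-test of genotypic association between two loci.

    Input is one ((a1, a2), (b1, b2)) entry per sample typed at both loci.
    The statistic is the G-statistic of the genotype-by-genotype contingency
    table; the null distribution permutes one locus's genotypes across
    samples.
    """
    if len(genotype_pairs) < 5:
        raise ValueError("need at least five samples typed at both loci")
    geno_a = [tuple(sorted(a)) for a, _ in genotype_pairs]
    geno_b = [tuple(sorted(b)) for _, b in genotype_pairs]
    if len(set(geno_a)) == 1 or len(set(geno_b)) == 1:
        return 1.0

    def g_stat(xs, ys) -> float:
        table = Counter(zip(xs, ys))
        row = Counter(xs)
        col = Counter(ys)
        n = len(xs)
        g = 0.0
        for (x, y), obs in table.items():
            exp = row[x] * col[y] / n
            g += 2.0 * obs * math.log(obs / exp)
        return g

    observed = g_stat(geno_a, geno_b)
    rng = np.random.default_rng(seed)
    perm_b = list(geno_b)
    exceed = 0
    for _ in range(reps):
        rng.shuffle(perm_b)
        if g_stat(geno_a, perm_b) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (reps + 1)


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm-adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(ps, method="holm")
    return [float(p) for p in adjusted]


def richness_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with the two-sided t-test p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three populations")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def population_summary(
    genotypes: PopulationGenotypes,
    population: str,
    loci: Sequence[str],
    catalog: Optional[AlleleCatalog] = None,
    rarefaction_g: Optional[int] = None,
    ci_pool: Optional[Mapping[str, int]] = None,
    ci_reps: int = 10_000,
    seed: Optional[int] = None,
) -> PolymorphismSummary:
    """Assemble the per-population summary row across ``loci``.

    Sequence-level statistics (Hd, S, pi, k) are computed only when a
    single-locus ``catalog`` is supplied and that locus is in ``loci``.
    """
    per_locus_counts = [genotypes.allele_counts(population, locus) for locus in loci]
    per_locus_counts = [c for c in per_locus_counts if c]
    if not per_locus_counts:
        raise ValueError(f"no typed data for population {population!r}")
    A = float(np.mean([len(c) for c in per_locus_counts]))
    if rarefaction_g is None:
        rarefaction_g = min(sum(c.values()) for c in per_locus_counts)
    A_R = multilocus_richness(per_locus_counts, rarefaction_g)

    n_samples = max(genotypes.sample_size(population, locus) for locus in loci)
    h_o = float(
        np.mean([observed_heterozygosity(genotypes, population, l) for l in loci])
    )
    h_e = float(np.mean([expected_heterozygosity(c) for c in per_locus_counts]))

    hd = s = pi = k = None
    if catalog is not None and catalog.locus_name in loci:
        counts = genotypes.allele_counts(population, catalog.locus_name)
        hd = haplotype_diversity(counts)
        s, k, pi = pairwise_diff_stats(catalog, counts)

    ci = None
    if ci_pool is not None:
        ci = allele_count_ci_permutation(
            ci_pool, n_samples, reps=ci_reps, seed=seed
        )

    return PolymorphismSummary(
        population=population,
        N=n_samples,
        A=A,
        A_R=A_R,
        ci_NA=ci,
        H_O=h_o,
        H_E=h_e,
        Hd=hd,
        S=s,
        pi=pi,
        k=k,
    )
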