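# Methods

This note records the statistical models, numerical conventions and design
choices behind `immunopop`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Genotype validation from clones

PCR-and-clone genotyping of a single-locus MHC amplicon is vulnerable to
polymerase error and chimera formation, so a clone sequence only counts as
an allele once it has been isolated from **two independent PCR reactions**;
the two reactions may come from the same individual or from different
individuals (`validate_clone_genotypes`). A sample whose accepted alleles
number more than two is excluded entirely (possible cross-contamination or
locus duplication) and reported in `rejected_samples`; a sample with no
accepted allele is left untyped rather than treated as an error. The filter
is order-independent and monotone: adding clone observations can only grow
the accepted-allele set.

## Polymorphism statistics

Two program lineages in this field use different small-sample conventions,
and both appear in published tables. `immunopop` therefore exposes both
explicitly:

* expected heterozygosity `H_E = 1 − Σp²` is **uncorrected** by default
  (`unbiased=True` applies 2N/(2N−1));
* haplotype (gene) diversity `Hd` always carries the n/(n−1) factor.

With Otawa-like counts {36, 2} these give 0.100 and 0.102 respectively —
two legitimately different numbers for the same data.

`pairwise_diff_stats` computes segregating sites S, the copy-weighted mean
pairwise difference count k (over all C(n,2) gene-copy pairs), and
π = k/L. Gap handling is pairwise deletion: an alignment column with a gap
or N in either member of a pair is skipped for that pair; L counts columns
with ≤ 50% gaps among the alleles present. π·L = k holds identically.

**Allelic richness** uses hypergeometric rarefaction,
`Σ_i [1 − C(N−N_i, g)/C(N, g)]`, verified against exhaustive subsample
enumeration. The default gene-copy base g is 2 × min(N) across the
populations of a marker set, computed separately per marker set. The
**permutation CI** for the expected allele count at a given sample size
draws 2N copies without replacement from the allele copies pooled across
all analyzed populations of the locus (10,000 replicates, percentile CI,
seeded); pooling across populations is this package's reading — the
composition of the reference pool is a genuine degree of freedom.

**Hardy–Weinberg tests** are exact tests on the Levene distribution of
genotype configurations conditional on allele counts,

P({n_ij}) = N! Πn_i! 2^h / ((2N)! Π n_ij!),  h = number of heterozygotes.

The global alternative sums configurations no more probable than the one
observed; `het_deficit` sums configurations with at most the observed
heterozygote count. Enumeration is exhaustive while the visited
configuration space stays under 10⁶ (skipped outright above 10 alleles);
beyond that the null is sampled by shuffling the gene-copy multiset and
pairing consecutive copies — an *exact i.i.d. sampler* for the same
conditional distribution. This replaces the more common genotype-swap MCMC:
it needs no burn-in or mixing diagnostics and is unbiased by construction.
Monte-Carlo p-values use the (1 + hits)/(reps + 1) estimator.

**Linkage disequilibrium** between loci is a permutation G-test on the
genotype-by-genotype contingency table, permuting one locus's genotypes
across individuals. **Holm–Bonferroni** adjustment is delegated to
statsmodels. The richness regression is ordinary least squares with the
two-sided t-test on the slope (n − 2 df).

## Differentiation

Within/total gene diversities weight populations equally (H_T uses the
unweighted mean frequency vector, Nei–Chesser convention). The naive
estimators use plain frequencies and admit closed-form checks — naive
Jost's D is exactly 1 for disjoint pools, 0 for identical frequency
vectors, and G'_ST ≥ G_ST always. The bias-corrected estimator applies
H_S_est = (Ñ/(Ñ−1))·H_S and H_T_est = H_T + H_S_est/(2Ñn), Ñ the
harmonic-mean diploid sample size; corrected values can be slightly
negative and are reported unclipped.

Pairwise matrices compute each pair with n = 2 demes and average across
loci arithmetically (a harmonic-mean combiner is available; which one a
given published table used is often unknowable, so both are exposed). A
locus monomorphic across a pair contributes 0 under the naive estimator
and is skipped (undefined) under the corrected one. Supertype-level
differentiation reuses the same code path with an allele→class mapping, so
it agrees exactly with direct evaluation on the mapped counts.

The Mantel test correlates upper-triangle entries under simultaneous
row/column permutation (two-sided, (1 + hits)/(reps + 1)); it is
implemented in-package so a seed controls the permutation stream, and its
r is cross-checked in the tests against scikit-bio's implementation.
Geographic distances are great-circle kilometers from decimal lat/lon.

## Selection and recombination

**Nei–Gojobori counting.** Synonymous site counts per codon are the
per-position fractions of the three single-nucleotide fates preserving the
amino acid; mutations to stop codons count as nonsynonymous so that
S + N = 3 × codons. Multi-step codon differences are averaged over all
minimal pathways, excluding pathways through stop codons unless every
pathway is. All 64×64 pair counts are precomputed, so pairwise statistics
are table lookups.

**Codon Z-test.** dN and dS are the means of pairwise proportions over all
sequence pairs; the SE of dN − dS is bootstrapped over codon sites
(default 1000 seeded replicates); the p-value is the one-tailed normal tail
for positive selection. The test is invariant to sequence order.

**Single-breakpoint scan.** Candidate breakpoints sit at every variable
column with ≥ 20 columns on either side. For each candidate,
neighbor-joining trees (Jukes–Cantor distances, negative branch estimates
clipped at zero; p-distances ≥ 0.749 mapped to distance 5) are fitted to
the left and right segments and segment log-likelihoods are computed by
Felsenstein pruning under Jukes–Cantor with the NJ branch lengths (no
branch re-optimization — a deliberate desk-scale approximation of the
likelihood machinery in phylogenetic packages). Model scores are
AICc = −2LL + 2k + 2k(k+1)/(n−k−1) with k = branch count (+1 rate) and
n = alignment columns; a breakpoint is supported when the best two-tree
AICc beats the single-tree AICc. Segment p-distances come from prefix sums,
so the scan is O(pairs) per candidate. When the two-tree model has more
parameters than columns (e.g. 74 sequences on a 219-nt fragment) AICc is
undefined and the scan returns "unsupported" — a stated limitation of
information criteria at this sequence-to-length ratio.

**SLAC-style site counting.** Ancestral codons are reconstructed on the NJ
tree (or on the two segment trees when a supported breakpoint is supplied;
a codon belongs to the left segment when its last nucleotide is at or
before the breakpoint) by a Sankoff pass over the 61 sense codons with
cost 1000 per nucleotide step plus 1 per unavoidable nonsynonymous step —
i.e. minimize changes first, then nonsynonymous changes — with remaining
ties broken toward the lexicographically smallest codon. Observed per-site
synonymous/nonsynonymous changes are summed over branches
(pathway-averaged per branch), so the per-site totals equal the parsimony
change count. The per-site p-value is the one-tailed binomial tail
P(X ≥ nonsyn | total, p = N_sites/3): counting methods test against the
neutral expectation, and the one-tailed form is the directional test for
positive selection. Invariant codons return p = 1.

**REL and MEME are not re-implemented.** They are heavyweight random- and
mixed-effects phylogenetic codon models; their per-site outputs enter as
`SiteSelectionTable` rows. The consensus rule flags a site per model when
SLAC p < 0.05, REL Bayes factor > 100, or MEME p < 0.05, and retains sites
flagged by ≥ 2 distinct models. Relaxing any threshold can only grow the
set.

## Supertypes

Positively selected residues are encoded with the five z-scale descriptors
(the 20×5 constant table ships as `data/z_descriptors.tsv`); all other
residues are excluded. A gap residue at a selected site encodes as the
5-dimensional zero vector (this only matters if an indel site is ever
selected). Clustering is DAPC-style: columns are centered (not scaled —
unit-variance scaling would compress the between-cluster separation on
exactly the axes that carry it), PCA retains the components reaching the
variance target (floored at 3 axes: a one-dimensional retained space lets
k-means profitably bisect a single Gaussian cluster), k-means runs for
k = 1..k_max with 25 seeded restarts, and
BIC(k) = n ln(W_k/n) + k·d·ln(n) — the spherical k-means form in which
each cluster contributes one d-dimensional center. The chosen k is the
smallest within ΔBIC ≤ 2 of the minimum (ties toward smaller k), and final
labels come from a linear discriminant projection of the retained
components. The simpler penalty k·ln(n) was rejected because it keeps
rewarding splits of genuinely unclustered data, inflating k on constructed
well-separated-cluster benchmarks.

Supertype frequencies per population are allele copy counts mapped through
the assignments and renormalized.

## Synthetic data

The generator reproduces the *structure* of a fragmented five-population
amphibian survey: default sample sizes (18, 41, 22, 21, 19) diploids,
per-population MHC allele pools of (14, 29, 21, 11, 2) alleles with 4%
sharing between adjacent populations only, 73-codon coding alleles, nine
microsatellite loci with 2–5 alleles, and a within-population inbreeding
coefficient f_is = 0.4 that produces the heterozygote deficit expected
when null alleles segregate (Otawa-like single-pool populations stay in
equilibrium automatically). One root seed spawns independent substreams
per stage, so outputs are byte-identical per configuration and adding a
stage never perturbs another.

Coding alleles descend from one random ancestral sequence along a random
join genealogy with exponential branch increments. Substitution proposals
arrive at a rate scaled by max(1, ω) per codon; a synonymous proposal is
accepted with probability min(1, 1/ω) and a nonsynonymous one with
min(1, ω), so the synonymous rate stays at the base rate for every ω while
the nonsynonymous rate is ω times it. Defaults: ω = 5 at 11 selected
codons, ω = 0.5 elsewhere (weak purifying selection on framework
residues), and a tree depth scale of 0.03 chosen to give catalog-wide
nucleotide diversity near 0.09 — the hyperpolymorphic regime of real MHC
fragments. Optional recombinant alleles splice two donors at a fixed
breakpoint (default nucleotide 162, 15% of alleles). With
`spatial_decay > 0` populations sit equally spaced on a line and
microsatellite frequencies drift stepwise along it, producing genuine
isolation by distance for Mantel power tests.

**What the synthetic data do not show.** The generator does not model
coalescent recombination, stepwise microsatellite mutation, genotyping
dropout, or — importantly — *motif structure* at the selected residues:
simulated alleles spread smoothly in descriptor space, so the supertype
stage on synthetic catalogs typically and correctly reports a single
cluster. Cluster-number recovery is therefore benchmarked on constructed
descriptor-space clusters, and a multi-supertype result on real data is
not validated end-to-end here. Passing tests demonstrate correctness of
the estimators and the stated statistical properties at the simulated
effect sizes, not field realism.

## Test problem sizes and statistical choices

Power-style properties use fixed seed batches: breakpoint recovery and
specificity use 50 two-tree/single-tree alignments of 30 sequences × 300
nt at rate 0.08 (recovery within ±15 nt and false-positive rate ≤ 10%);
cluster-number recovery uses 50 four-cluster descriptor datasets; the
Hardy–Weinberg type-I rate uses 200 three-allele populations of 25
diploids (exact discrete tests are conservative, so the observed rate sits
at or below the nominal 5%). The global Z-test power benchmark places
strong selection (ω = 20) on ~30% of codons: at the study-like default of
11 selected codons in 73 the global statistic is honestly marginal — as it
is in real MHC fragments of this size — because site-level saturation and
the between-codon bootstrap variance cap the attainable Z. The SLAC
recovery benchmark likewise uses ω = 10 at elevated divergence; at ω = 5
and study-scale divergence the counting test flags only a minority of the
true sites, which reflects the method's well-known conservatism rather
than an implementation defect.

## Known limitations

* NJ + Jukes–Cantor with fixed branch lengths approximates ML tree
  machinery; no substitution-model selection is performed.
* The SBP scan cannot support a breakpoint when the two-tree
  parameterization exceeds the number of columns (many-sequence short
  alignments); a sliding-window or subsampled variant would be needed
  there.
* Bias-corrected diversity components follow the Nei–Chesser-style forms
  stated above; other software lineages differ in the finite-sample term,
  so third-party tables may differ in the second decimal.
* The permutation CI's pooling scheme and the multi-locus combining rule
  (arithmetic vs harmonic) are stated choices; alternatives are exposed as
  options rather than silently fixed.
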