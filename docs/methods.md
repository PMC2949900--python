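# Methods

## Setting and notation

A *collection* is a set of studies measuring the same genes under two
conditions, `normal` and `disease`. A study is *symmetric* when it
contains samples of both conditions and *asymmetric* otherwise. Two
estimation strategies are implemented over a collection:

1. **Inverse-variance (IV) meta-analysis** — analyse each symmetric
   study separately, then pool the per-study standardized effects.
   Asymmetric studies have no within-study contrast and are rejected by
   construction.
2. **Merged SAM** — put every array of every study on one common scale,
   concatenate all samples into a single genes × samples table, and run
   one two-class SAM test on the pooled design. Asymmetric studies
   contribute their samples like any other.

The package's purpose is to make both strategies, and the statistics
used to compare their outputs, available on the same data structures.

## Normalization

### Per-cohort RMA

`rma_summarize` applies the standard pipeline to a probe-level table:
background adjustment (a constant offset subtraction floored at 1 so
log₂ stays defined; default offset 0, i.e. a no-op — the convolution
background model is deliberately out of scope), quantile normalization
across the cohort's arrays, log₂ transform, and per-gene median polish
of the additive model

    T(PM_ij) = e_i + a_j + ε_ij,

reporting `m + e_i` per gene and array. Median polish runs at most 10
sweeps to a tolerance of 0.01 log₂ units (common RMA practice). Probe
effects are median-centred within each gene; this is the identifiability
convention for `e`, and the synthetic generator uses the same one.

Quantile normalization maps each column's sorted values onto the
across-column mean of sorted values. Ties receive the mean of their
target quantiles, which makes the output invariant to sample order and
to the permutation of tied entries.

### Frozen-reference normalization

`refrma_train` pools a training cohort and freezes two vectors: the
reference quantile vector (mean sorted background-adjusted intensity
vector) and the per-probe affinity vector `a_j` from per-gene median
polish of the pooled, quantile-normalized, log₂ data. `refrma_apply`
then normalizes arrays *one at a time*: rank-map the array onto the
reference quantiles (linearly interpolating the reference's empirical
quantile function when the array carries fewer probes, which is how a
model trained on a large chip extends to smaller chips sharing a probe
subset), subtract `a_j` on the log₂ scale, and summarize each gene as
the median over its probes. Because each array is processed
independently, adding arrays never changes existing output — the
property that makes incremental multi-study merges coherent.

The `qq_concordance` statistic (maximum absolute difference and Pearson
correlation of paired empirical quantiles) quantifies what the frozen
reference buys: arrays from different studies normalized per-study
retain their lab shifts, while reference-normalized arrays are forced
onto one distribution. The acceptance suite verifies this contrast on
synthetic data over 20 seeded replicates.

### Merged gene-level tables

When the merged analysis starts from gene-level tables rather than probe
intensities, `merged_sam` jointly quantile-normalizes the merged columns
before testing (the gene-level analogue of referencing every array to
one distribution). This step matters: study-level location shifts are
orthogonal to class in a balanced symmetric design, but become
confounded with class as soon as asymmetric studies join the merge.
Without the joint normalization the merged design loses its advantage;
with it, asymmetric samples add power. Callers supplying data already
normalized against a frozen reference pass `normalization=None`.

## SAM

For gene *i* with disease/normal means `x̄₁, x̄₂` and within-class sums
of squares `SS₁, SS₂` over `n₁, n₂` samples:

    r_i = x̄₁ − x̄₂
    s_i = sqrt[(1/n₁ + 1/n₂) · (SS₁ + SS₂)/(n₁ + n₂ − 2)]
    d_i = r_i / (s_i + s0)

The fudge factor `s0` is chosen from the percentiles {0, 5, …, 100} of
`s` to minimise the coefficient of variation of the median absolute
deviation of `d` across 100 `s`-quantile windows — the standard recipe
for stabilising low-variance genes. The search is deterministic; a
degenerate all-equal `s` yields `s0 = 0` (any value would only rescale
`d`). Genes with `s_i + s0 = 0` score 0.

The null is label permutation with `s0` held fixed: all distinct
arrangements are enumerated when `C(n, n₁)` is at most 10× the requested
permutation count (so small designs are exact), otherwise arrangements
are sampled. Permutations deliberately ignore study membership — the
merged design treats all samples as exchangeable under the null; a
study-stratified option would be a different null and is not the default.

Calling at threshold δ follows the order-statistic rule: with observed
order statistics `d_(i)` and their permutation means `d̄_(i)`, the
smallest `d_(i)` with `d_(i) − d̄_(i) > δ` opens the upper calling
region and the largest with deviation `< −δ` the lower. The estimated
FDR is the median over permutations of the number of permuted scores
beyond the cutoffs, divided by the number of called genes (0/0 → 0).
"FDR 0" therefore means: the largest call set whose *estimated* FDR
under the finite permutation set equals zero — an estimate, not a
guarantee. The null-proportion (pi0) rescaling of the FDR is available
(`SamConfig(pi0_scaling=True)`) but off by default, since the unscaled
median-false-count estimate is the conservative baseline.

Ranked lists order genes by |score| descending, ties broken
lexicographically by gene id, and are restricted to called genes — so a
list may stop short of its nominal cutoff when few genes pass, and all
downstream statistics use the effective list size.

## Inverse-variance meta-analysis

Per symmetric study, the standardized mean difference (disease minus
normal, so IV and SAM scores share sign):

    d = (x̄₁ − x̄₂)/s,   s = sqrt[((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)]

with the large-sample variance `var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`.
No small-sample (Hedges) correction is applied by default — the plain
`d` is the reported quantity — but `hedges=True` applies the usual
shrinkage factor. Fixed-effect pooling uses weights `1/var(d)`; the
pooled effect's normal z gives a two-sided p, and Benjamini–Hochberg
(via statsmodels) thresholds at `q* = 10⁻⁵` by default (an FDR of
0.001%). Genes measured by only a subset of studies are pooled over
those studies, with `k_studies` recording how many contributed; genes
with zero pooled SD in a study are flagged undefined and excluded from
that study's contribution with a warning.

## Validation statistics

**Top-k overlap.** The intersection of two rankings' top-k genes is
referred to the hypergeometric distribution over an *explicit* universe
size N (never silently inferred from list contents): the upper tail
P(X ≥ observed), summed in log space so that tails below 10⁻²⁰⁰ remain
representable. Overlap 0 gives p = 1 under this convention.

**Literature-hit score.** Given an offline gene → abstract-count table,
a list's score is the number of its genes with count ≥ 1. The null is
resampling: 100 random equal-size gene lists from the universe, scored
the same way; their mean and SD parameterise a normal upper tail. Lists
shorter than their nominal cutoff are compared against random lists of
the effective size. The per-gene query template
(`<SYMBOL> AND cancer NOT microarray`) is provided for provenance and
formatting only; nothing in the package performs network access, and
genes absent from the hit table count zero. The normal approximation
makes the p-value slightly anti-conservative in the extreme tail of a
discrete count; the calibration test bounds the miscalibration at the
0.1 level.

## Synthetic data

The generators emulate the structure that makes multi-study integration
hard, and nothing more:

- gene-level value = `μ_g + b_d + 1[disease]·δ_g·σ + N(0, σ)` with
  baseline `μ_g ~ N(8, 1.5)` log₂ units (a typical summarized-intensity
  range), per-study lab shift `b_d ~ N(0, 0.5)` log₂ units by default,
  within-class noise σ = 0.25 log₂ units, and planted standardized
  effects `δ_g` (mean |δ| 1.5, random sign, on a `de_fraction` of genes —
  effects are expressed in units of σ so they are directly comparable to
  the standardized-effect estimates);
- probe-level intensity = `2^(e + a_j + ε) + max(0, background)` with
  affinities `a_j ~ N(0, 0.5)` drawn once per probe, median-centred
  within gene, and held fixed across arrays;
- hit tables mark genes with probability `base_rate`
  (+ `de_boost` for planted genes); positive counts are 1 + Poisson(2),
  though only count ≥ 1 matters downstream.

What the generator does *not* model — probe-level MM effects, spatial
artifacts, dye bias, correlated gene modules, heavy-tailed noise,
platform-specific probe sets beyond a simple subset option — bounds what
passing tests show: they demonstrate correctness of the estimators and
the claimed qualitative contrasts under an additive lab-shift model, not
robustness to every artifact of real chips.

## Experiment sizes and numerical choices

Simulation-based checks run at desk scale, chosen so the full suite and
the acceptance script each finish in well under their budgets on one
CPU: IV recovery uses 20 collections of 5 studies (10v10, 150 genes,
δ = 1); SAM recall uses 3×10v10 with 1000 genes and 5% planted effects
at |δ| = 1.5, scoring the top-2×planted list; the merged-advantage and
frozen-reference contrasts use 20 seeded replicates each; literature
calibration uses 200 random lists of 100 genes over a 2000-gene
universe. The purely-asymmetric perturbation experiment enumerates all
2^k one-condition deletions over k ≤ 12 symmetric studies (3 in the
tests) and compares the variant-averaged hit count against the full
merged run's; hit-table rates there are base 0.3 / boost 0.5, giving the
enrichment z enough margin that the qualitative contrast, not hit-table
binomial noise, drives the comparison.

Other numerical conventions: all gene and sample orderings are
lexicographic for byte-reproducibility; every stochastic routine takes
an explicit seed and identical seeds give identical output; degenerate
cases are defined explicitly (empty call set → FDR 0; zero null SD →
literature p ∈ {0, 1}; overlap 0 → p 1; zero-scatter genes flagged
rather than silently dropped).

## Known limitations

- The IV engine is fixed-effect only; heterogeneity across studies is
  not modelled (no random-effects variance component).
- The frozen-reference background step is a constant-offset subtraction,
  not the normal+exponential convolution; training cohorts with strong
  background gradients would need the fuller model.
- The literature score depends entirely on the supplied hit table; the
  package ships no corpus and performs no retrieval.
- The purely-asymmetric experiment enumerates 2^k designs and is capped
  at k = 12 symmetric studies; larger collections need a sampling mode.
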