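# Methods

## Statistical model

Counts k_ij (gene i, sample j) are modelled as negative binomial with
mean s_j·q_i and variance μ + αμ². The package uses the
(mean, dispersion α) parameterization everywhere, including the
generators, so estimates and truth tables are directly comparable.

### Size factors

s_j = median over genes of k_ij/(∏_v k_iv)^(1/m), restricted to genes
with strictly positive counts in every sample. If no gene is positive
everywhere, estimation refuses with an instruction to filter; silent
fallbacks would change the estimand. Note the exact invariances: the
factors are unchanged when every sample is scaled by a common constant
(the geometric-mean pseudo-reference scales along), and scaling a single
sample by c scales its factor by c^((m−1)/m) and every other factor by
c^(−1/m).

### Dispersion estimation

Per-gene raw dispersions come from pooled method-of-moments on
normalized counts: pooled within-condition variance (over conditions
with ≥2 replicates, df = #replicated samples − #replicated conditions)
minus the shot-noise term mean(1/s_j)·baseMean, divided by baseMean²,
floored at 0. A parametric curve α(μ) = a₀ + a₁/μ is fitted to genes
with positive raw dispersion by gamma-family IRLS with identity link
(working weights 1/μ̂², relative coefficient tolerance 1e-8, max 100
iterations). Final per-gene dispersion is max(raw, fitted) — "maximum"
sharing: the curve acts as a lower bound so genes whose few replicates
happen to agree are not assigned implausibly small dispersions. On
IRLS failure (non-convergence or negative coefficients) the fit falls
back to a least-squares line through tercile medians of
(1/mean, dispersion), with a logged warning. The configuration
(pooled / parametric / maximum) is recorded in run reports.

Consequence worth knowing: maximum-sharing biases testing dispersions
upward, so the exact test is mildly conservative at 3 vs 3 — measured
raw p < 0.05 fractions on 2000-gene null simulations cluster around
0.03 (0.025–0.039 across ten seeds) versus 0.04–0.06 when the true
dispersions are supplied. This is a property of the sharing rule, not a
defect of the test.

### Conditional exact NB test

For a contrast B vs A the condition-summed counts K_A, K_B are modelled
as NB with mean q̂·S_X (S_X = Σ s_j over the condition) and variance
q̂·S_X + α·q̂²·Σ s_j², floored at mean·(1+1e-8); q̂ is the pooled mean of
normalized counts over both conditions. Conditional on K = K_A + K_B,
the two-sided p-value sums the probabilities of all splits (a, K−a)
whose probability does not exceed the observed split's (ties within
relative 1e-12 included), normalized by the total conditional mass.
Enumeration is exhaustive up to K = 20000; beyond that, two windows
(around the conditional mode and around the observed split, ±40
conditional standard deviations) cover the mass to relative error
< 1e-60, verified against full enumeration in the tests.

Degenerate genes: both conditions all-zero → p = 1, log2fc = 0, flag
`untestable` (excluded from DE sets and signatures); one condition
all-zero → log2fc = ±inf sentinel, flag `infinite_fc`, and such genes
pass the fold-change filter by convention — an all-or-nothing gene is
maximally changed.

Fold-changes are log2(meanB/meanA) of normalized condition means; the
DE filter works on the linear ratio with the reciprocal pair
(fc_up = 2, fc_down = 1/2), both configurable.

### Multiple testing

Benjamini–Hochberg step-up, applied per contrast for DE and per
collection for enrichment, never pooled across analyses.

## Signature and scoring

The signature keeps every gene with padj < padj_max (default 0.05) in
the hypoxia-vs-untreated table and finite log2fc; no fold-change
magnitude filter is applied at this stage, so moderate but consistent
responders contribute. Scores are Σ w_g·t(x_gs) with t = identity by
default — the plain product of weight and expression; `log2p1` is
available because on RSEM-scale cohorts a few high-expression genes
otherwise dominate the sum. Signature genes missing from a matrix
contribute 0 and are counted per report; optional `mean` and `zscore`
post-processing are off by default. Outcome groups are compared with
the two-sided Wilcoxon rank-sum test.

## Rank-sum test

Midranks for ties. Exact p by enumerating the rank-sum distribution
(subset-sum dynamic programme) when n₁+n₂ ≤ 20 and the pooled sample is
tie-free — two-sided p doubles the smaller tail, capped at 1. Otherwise
a normal approximation with tie-corrected variance and continuity
correction (matching R's wilcox.test). p-values are floored at the
smallest positive double and formatted as "< 2.2e-16" below that
display floor. The breadth comparison between contrasts is unpaired by
default over the shared finite-fold-change universe (the R-default
reading of an unpaired "wilcoxon" on two fold-change distributions);
`paired=True` switches to the signed-rank test on per-gene differences.

## PCA

prcomp conventions: samples are observations, centering always,
variable scaling optional (off by default), SVD under the hood,
component signs fixed so each component's largest-magnitude loading is
positive. Cohort values are log2(x+1)-transformed by default before
centering — normalized RSEM-like scales are heavy-tailed and raw-scale
PCA is dominated by a handful of genes; `identity` is available.
Projection restricts to genes shared with the model and imputes missing
model genes at their centers (zero contribution after centering),
refusing below a 50% overlap (configurable).

## Synthetic data: what it emulates, what it does not

`simulate_counts` draws NB counts via gamma–Poisson mixing with
sample size factors uniform on [0.7, 1.4], baselines
q_i ~ logNormal(log 200, 1) (bulk RNA-seq at roughly 10M reads/sample),
dispersions (0.01 + 1/q_i)·logNormal(0, 0.2), and per-condition effect
architectures; the defaults plant the broad/moderate hypoxia program
(π = 0.3, |log2fc| ~ N(1, 0.3²), random sign) against the
narrow/strong CoCl₂ program (π = 0.02, |log2fc| = 3). `simulate_cohort`
draws log-normal expression (baseline N(log₂ 300, 1.5²) in log2 units,
within-group noise SD 1.0 log2 units), a tumour-vs-normal program on
30% of genes, an optional coupling of the tumour program to the
signature weights, and a shift of every signature gene by
`outcome_effect_sd` within-group SDs in the weight's direction for
recurred/progressed tumours.

Not emulated: batch effects, library-preparation biases, gene–gene
correlation beyond the planted programs, count-level structure in the
cohort (it is generated on the normalized scale), splice structure, and
any real pathway biology — GMT inputs in tests are constructed. Passing
tests therefore demonstrate statistical correctness and calibration of
the machinery under the stated generative model, not agreement with any
particular real dataset.

## Problem sizes and seeds

Simulation-backed checks use 2000 genes for DE-stage calibration and
recovery, 200 seeded replicates for null-uniformity of the outcome
comparison, 200 seeded instances for oracle agreement, and cohorts of
~50–110 samples — sizes at which the measured quantities are stable
across seeds while the whole suite stays quick. Every generator takes
an explicit seed and owns a single `numpy.random.Generator`; nothing
reads global RNG state. `scripts/acceptance.py` derives all sub-seeds
from its `--seed` argument.

## Known limitations

- Single-factor two-group contrasts only; no GLM designs, shrunken
  fold-changes, or independent filtering.
- The enrichment test is the plain hypergeometric upper tail; the
  jackknifed Fisher variant used by some web services is deliberately
  not replicated.
- Maximum-sharing conservativeness at n = 3 vs 3 (above).
- The exact rank-sum path is limited to n₁+n₂ ≤ 20 tie-free samples;
  beyond that the tie-corrected normal approximation is used (agreement
  within |Δp| ≤ 0.02 at 10+10 in the tests).
- Gene identifiers are opaque strings; no ID translation is attempted,
  so signature, cohort and pathway inputs must share a namespace.
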