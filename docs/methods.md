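# Methods

## The question and the data layout

Serial immunophenotyping of healthy adults yields, per individual *i*,
visit *j* and cell subset *s*, a frequency `y_ijs` expressed as % of the
subset's parent gate. The analyses here ask, subset by subset: how much of
the population variance is a stable personal baseline versus short-term
fluctuation; whether fluctuation is coupled to baseline (the signature of
an environmentally responsive subset); how subsets co-vary across
individuals; and whether siblings share baselines. All stages consume
long-format CSV tables validated against fixed schemas (one row per
observation; strict mode rejects any invalid row naming it, lenient mode
drops and logs).

## Normalization

Subset frequencies span orders of magnitude, so raw variances are not
comparable across subsets. Two scale corrections are used, matching the
stage that consumes them:

- **mean-normalization** (`value = y / mean_s(y)`), used for all variance
  decomposition — variances of mean-normalized values are squared
  coefficients of variation, comparable across subsets;
- **z-scoring** (`z = (y − mean_s)/sd_s`, n−1 SD), used for the
  baseline/fluctuation analysis and pair distances — it additionally
  equalizes between-individual spread across subsets.

Both are computed over the longitudinal cohort only; the sibling cohort is
z-scored against its own mean/SD, which absorbs cohort-level batch
differences. Sample variances use the n−1 denominator throughout.

## Variance decomposition

`var_between` is the variance across individuals of per-individual means
(not the pooled variance of all observations; individuals with a single
visit contribute their one value as their mean). `var_within` is the
unweighted mean of per-individual sample variances over visits, restricted
to individuals with ≥2 visits — the design is near-balanced so weighting
is immaterial. `var_technical` is the variance across staining runs of the
mean-normalized control sample.

The model-based partition fits the one-way random-intercept model
`y_ij = μ + b_i + e_ij` by REML. For this model the restricted likelihood
can be profiled over μ and σ²_w analytically, leaving a one-dimensional
criterion in the variance ratio λ = σ²_b/σ²_w, which is bracketed on a log
grid and minimized by bounded Brent search (`xatol` 1e-13). On balanced
data with an interior optimum this reproduces the ANOVA closed form
(σ̂²_w = MSW, σ̂²_b = (MSB−MSW)/n) to better than 1e-8; the test suite also
cross-checks against an independent general-purpose mixed-model fitter on
unbalanced data. At the λ = 0 boundary the estimate is reported truncated
with a flag — note that there the REML residual variance is the pooled
SS/(N−1), not MSW, which only coincides in the interior. Degenerate
(all-equal) inputs return both components 0 with `prop_within` flagged
undefined.

Subsets whose technical variance exceeds the Tukey far-out fence
(Q3 + 3·IQR, type-7 quantiles) are excluded from downstream stages but kept
in reports. With ~40 replicate runs the per-subset variance estimates have
CV ≈ 0.22, so the fence occasionally (a few percent of subsets) flags a
merely unlucky subset in addition to genuinely noisy ones; exclusion
decisions are recorded in `exclusions.json` so they can be audited.

The within-on-between regression is plain OLS of `var_within` on
`var_between` across subsets (optionally adding `var_technical` as a
covariate), reporting the slope, adjusted R² and the t statistic of the
between-variance coefficient.

## Resampling tests

**Variance permutation test.** The statistic is `T = var_between −
var_within` (a difference, not a ratio, so constant-within individuals do
not divide by zero). The null permutes individual labels over all
observations of the subset, preserving each individual's visit count; when
the number of distinct labeled assignments is no larger than the requested
permutation count the null is enumerated exhaustively and the p-value is
the exact fraction, otherwise Monte-Carlo draws are used with the add-one
convention `p = (1 + #{T_null ≥ T_obs})/(B+1)` (one-sided: between exceeds
within). Under σ²_b = 0 the observations are exchangeable and the test is
exactly calibrated; the acceptance suite verifies a rejection rate within
[0.035, 0.065] at α = 0.05.

**Sibling concordance.** Both cohorts are z-scored separately; all
within-family pairs contribute (families with <2 members are dropped with a
notice); the statistic is the mean |Δz| over sibling pairs. The null
resamples the same number of **disjoint** unrelated pairs without
replacement from a single-visit reference cohort; `p = (1 + #{null ≤
obs})/(B+1)` (one-sided: concordance = smaller distance). A reference of
size R can only supply ⌊R/2⌋ disjoint pairs, so at the default study scale
(37 families vs a 43-individual reference) the pipeline falls back, with a
logged notice, to sampling pairs independently (each pair still two
distinct individuals); calibration simulations instead use an
80-individual reference so the disjoint-pair null is feasible. The
calibration of this null is sensitive to heavy-tailed marginals: if the
values were purely lognormal with large log-SD, the fixed reference could
not represent cross-cohort variation in extremes and null p-values would
be over-dispersed; under the generator's default noise structure the null
is uniform to Kolmogorov–Smirnov precision at 500 simulations.

Batch modes run every subset with per-subset random streams derived from
the master seed and append Benjamini–Hochberg q-values.

## Baseline–fluctuation coupling

Per individual and subset, the mean of the z-scores is the baseline and
their sample variance the fluctuation (individuals with one visit get no
fluctuation). Spearman's ρ between the two across individuals uses average
ranks for ties; the two-sided p-value uses the t approximation for n ≥ 10
and exact enumeration of all rank permutations below that. The rank
concordance between per-subset `var_between` and per-subset coupling ρ is
again Spearman. The figure-legend definition of fluctuation (variance of
z-scores) is used rather than the loose "variance normalised to the mean"
phrasing; both describe the same quantity up to the per-subset scale
already removed by z-scoring.

## Multivariate structure

PCA operates on individuals × features matrices built from the
fluctuation summary (baselines, fluctuations, or both concatenated),
column-centered and by default unit-scaled, decomposed by SVD; component
signs are fixed so each component's largest-magnitude loading is positive,
making outputs reproducible. Correlation matrices are pairwise Spearman
with BH-FDR computed over the strict upper triangle (m = k(k−1)/2) and
mirrored; constant features are flagged undefined rather than failing the
whole matrix. The network view keeps edges with q below and |ρ| above
thresholds; an optional flag drops pairs sharing a parent gate, whose
negative correlations are compositional artifacts. Sex comparisons
collapse each individual to their mean over visits, then apply the
two-sided Mann–Whitney test (exact null for combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise) with Bonferroni adjustment.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every calibration claim refers to: 43 individuals × 4 quarterly
visits × 35 subsets, ~40 technical replicate runs (CV 4%), 37 two-sibling
families. Per subset *s* and individual *i*:

```
b_is ~ N(0, σ²_b)                          stable log-scale baseline
e_ijs ~ N(0, (σ_w · exp(κ·b_is))²)         visit fluctuation
y_ijs = clamp(μ_s · (exp(b_is) + e_ijs), 0, 100)
```

Baselines are lognormal across individuals (positive, right-skewed, scale
set by μ_s which spans 0.08–80% across the catalog). The fluctuation is
additive at the subset scale: this is deliberate, because multiplicative
visit noise would make every individual's fluctuation proportional to
exp(b) and hence make *every* subset baseline-fluctuation coupled — κ
would then not distinguish responsive from stable subsets. With the
additive form, κ = 0 gives identical visit spread for everyone (no
coupling) and κ = 1 reproduces the responsive signature. Useful closed
forms under κ = 0 and no clamping: E[y] = μ·exp(σ²_b/2); on the
mean-normalized scale the between component is e^{σ²_b} − 1 and the within
component σ²_w·e^{−σ²_b}.

The default catalog assigns each subset a dispersion class (low 0.15 / mid
0.30 / high 0.50 log-SD between individuals) with the within/between SD
ratio cycling over 0.4–0.7 for stable subsets — one shared scale driving
both dispersions, which is what produces the strong within-on-between
regression — and 0.95 for the six responsive subsets (plasmablast-,
TEMRA-, γδ-T- and inflammatory-monocyte-like), which also get κ = 1. κ has
no published effect-size estimate; κ = 1 is a calibration choice giving
coupling ρ ≈ 0.5–0.7 at 43 individuals, the magnitude seen in responsive
subsets. The iNKT-like subset gets an 8× technical-CV multiplier so the
technical-outlier exclusion path is exercised under defaults. Technical
noise is lognormal with exact CV (log-SD √log(1+cv²)). Sibling baselines
are g_f + u_is with variances split f : (1−f) by the shared fraction f, so
the within-family correlation of log-baselines equals f. Each table draws
from its own stream derived from the master seed by fixed offsets, so
generating one table never perturbs another; clamping events are counted
in the truth manifest and logged (≈0.5% of observations under defaults,
almost all in high-μ subsets hitting 100 or rare responsive subsets
touching 0).

What the generator does **not** emulate: inter-subset correlations (the
catalog's subsets are statistically independent, so correlation networks
on synthetic data are empty — the network code is exercised on constructed
matrices), compositional closure between siblings of a parent gate,
seasonality, age/sex effects, and specific exposures. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the assumed hierarchical model, not the biological
richness of real cytometry data.

## Problem sizes and numerical choices

Calibration experiments run at the study scale where the claim concerns
the study design (type-I error of the permutation test: 1000 cohorts × 199
permutations; coupling detection: 200 cohorts per κ arm; sibling null and
power: 500 / 200 cohorts with 199 resamples). The structural
within-on-between check instead uses 120-individual cohorts: at 43
individuals the per-subset variance estimates are noisy enough (heavy-
tailed lognormal baselines) that adjusted R² fluctuates between ~0.6 and
~0.9 even under exact proportionality, masking the structural relation the
check is about.

Ties in permutation statistics are compared with a 1e-12 relative
tolerance so that floating-point reassociation cannot flip a ≥/≤
comparison. p-values from resampling are never 0 by the add-one
convention. Negative variance components are truncated at 0 and flagged;
`prop_within` is flagged undefined when both components vanish. The BH
step-up is implemented directly (and verified against an independent
implementation); q-values are clipped at 1 and NaN p-values propagate as
NaN without entering m.

## Known limitations

- The permutation scheme for the between-vs-within comparison is a
  reconstruction of an underspecified published procedure; it is the
  minimal exchangeability-based null consistent with permuting individual
  identity.
- The disjoint-pair sibling null requires a reference at least twice the
  pair count; below that the overlapping-pair fallback is slightly
  conservative in the null spread.
- REML standard errors are not reported (only point estimates and
  truncation flags); inference about variance ratios goes through the
  permutation test instead.
- The sex comparison uses per-individual means; it does not model
  repeated-measures correlation beyond that collapse.
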