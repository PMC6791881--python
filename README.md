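# cytomevar

Variance structure of longitudinal immune-cell subset frequencies.

Peripheral-blood immunophenotyping panels report dozens of cell subsets as
percentages of their parent gate. When the same healthy adults are bled
repeatedly over a year, each subset's population variance can be split into
a stable, person-specific *baseline* component and a short-term
*fluctuation* component — and that split is what separates subsets whose
levels are set by stable factors (heredity, early-life exposures) from
subsets that track the recent environment. `cytomevar` implements that
analysis end to end, together with a synthetic-cohort generator that makes
every stage verifiable without access to a real cohort.

## The model and statistics

For subset *s*, observations are first made comparable across subsets by
mean-normalization (divide by the subset grand mean) or z-scoring. On the
normalized values the package computes, per subset:

- **Descriptive variances** — `var_between` (variance of per-individual
  means), `var_within` (mean of per-individual variances across visits),
  `var_technical` (variance of a control sample across staining runs), with
  Tukey far-out fence exclusion of technically outlying subsets.
- **Variance components** — the one-way random-intercept model
  `y_ij = μ + b_i + e_ij`, `b_i ~ N(0, σ²_b)`, `e_ij ~ N(0, σ²_w)`, fitted
  by REML (the restricted likelihood is profiled down to a one-dimensional
  search over the ratio σ²_b/σ²_w); `prop_within = σ²_w/(σ²_b+σ²_w)` is the
  fraction of population variance due to within-individual fluctuation.
- **Permutation test** — `T = var_between − var_within` against the null
  obtained by permuting individual labels (exhaustive enumeration on tiny
  inputs), one-sided add-one p-value `p = (1 + #{T_null ≥ T_obs})/(B+1)`.
- **Baseline–fluctuation coupling** — per individual, the mean and variance
  of z-scores; Spearman's ρ between the two across individuals flags
  environmentally responsive subsets, and the rank concordance of that ρ
  with `var_between` across subsets tests whether the population-variable
  subsets are the responsive ones.
- **Multivariate structure** — PCA of individuals on baselines and
  fluctuations; pairwise Spearman correlation matrices with
  Benjamini–Hochberg FDR over the upper triangle; a thresholded correlation
  network; Mann–Whitney sex comparisons with Bonferroni correction.
- **Sibling concordance** — mean |Δz| over within-family pairs versus
  resampled unrelated pairs from one visit of the longitudinal cohort.

The synthetic generator draws, per subset, lognormal per-individual
baselines `exp(b_i)`, `b_i ~ N(0, σ²_b)`, and visit fluctuations additive at
the subset scale with SD `σ_w·exp(κ·b_i)` — the coupling coefficient κ is 0
for stable subsets and >0 for responsive ones — plus multiplicative
technical noise and a configurable shared-baseline fraction within sibling
families. A truth manifest records every latent value for
parameter-recovery testing.

## Worked example

```python
import cytomevar as cv
from cytomevar.variance import (mean_normalize, descriptive_variances,
                                add_variance_components,
                                regress_within_on_between)

config = cv.GeneratorConfig(seed=7)          # 43 x 4 x 35 synthetic study
obs, truth = cv.generate_cohort(config)
norm = mean_normalize(obs)
summary = add_variance_components(descriptive_variances(norm), norm)
print(summary["prop_within"].median())
print(regress_within_on_between(summary).adjusted_r_squared)
```

Running `python examples/02_variance_partition.py` (which adds replicate
normalization and outlier exclusion) prints:

```
technical-variance outliers (Tukey far-out fence): ['inkt']
...
median prop_within = 0.27 -> most variance is stable individual identity, not fluctuation

OLS var_within ~ var_between across 34 subsets: adj R^2 = 0.67, t = 8.3 ...
```

i.e. the technically noisy iNKT-like subset is excluded, roughly a quarter
of each subset's variance is short-term fluctuation, and subsets that
differ most between people also fluctuate most within them. The other
`examples/` scripts walk through the permutation test, coupling detection,
PCA/networks and the sibling test; each prints a line explaining what its
numbers mean.

A thin CLI wraps the same library:

```sh
cytomevar simulate --out-dir synthetic
cytomevar run-all --observations synthetic/observations.csv \
    --replicates synthetic/replicates.csv --siblings synthetic/siblings.csv \
    --catalog synthetic/catalog.csv --out-dir results
```

`run-all` writes every intermediate table (variance summary, permutation
and sibling test results, fluctuation summary, PCA scores, correlation
matrix, network edges) plus a machine-readable `summary.json`; identical
inputs, config and seed give a byte-identical bundle.

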