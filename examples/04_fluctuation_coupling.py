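"""Baseline-fluctuation coupling: the environmental-responsiveness signature.

z-score each subset, summarise each individual by mean (baseline) and
variance (fluctuation) of their z-scores, then correlate the two across
individuals.  Responsive subsets couple; stable subsets do not.
"""

import cytomevar as cv
from cytomevar.fluctuation import (individual_baseline_fluctuation,
                                   mean_variance_correlation_all,
                                   rank_concordance, zscore_transform)
from cytomevar.variance import descriptive_variances, mean_normalize

config = cv.GeneratorConfig(seed=7)
obs, _ = cv.generate_cohort(config)

fluct = individual_baseline_fluctuation(zscore_transform(obs))
mv = mean_variance_correlation_all(fluct).sort_values("spearman_rho",
                                                      ascending=False)
responsive = {s.subset_id for s in config.subsets if s.kappa > 0}

print("strongest baseline-fluctuation coupling (Spearman rho):")
for row in mv.head(6).itertuples():
    tag = "responsive" if row.subset_id in responsive else "stable"
    print(f"  {row.subset_id:18s} rho = {row.spearman_rho:+.2f} "
          f"p = {row.p_value:.2e}  [{tag} in truth]")

summary = descriptive_variances(mean_normalize(obs))
rc = rank_concordance(summary[["subset_id", "var_between"]], mv)
print(f"\nrank concordance between per-subset inter-individual variance and "
      f"coupling strength: rho = {rc.spearman_rho:.2f} (p = {rc.p_value:.3g})")
print("-> the most population-variable subsets are the environmentally "
      "responsive ones")
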