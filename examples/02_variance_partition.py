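"""Partition each subset's variance: between people, within people, technical.

Reproduces the descriptive variance table, the technical-outlier exclusion,
the random-intercept variance components, and the within-on-between
regression across subsets.
"""

import cytomevar as cv
from cytomevar.variance import (add_variance_components,
                                descriptive_variances, detect_outlier_subsets,
                                mean_normalize, regress_within_on_between)

config = cv.GeneratorConfig(seed=7)
obs, _ = cv.generate_cohort(config)
reps = cv.generate_replicates(config)

norm = mean_normalize(obs)          # divide by the subset grand mean
summary = descriptive_variances(norm, mean_normalize(reps))

flags = detect_outlier_subsets(summary, "var_technical")
excluded = flags.loc[flags["flagged"], "subset_id"].tolist()
print(f"technical-variance outliers (Tukey far-out fence): {excluded}")

kept = summary[~summary["subset_id"].isin(excluded)]
kept = add_variance_components(kept, norm[~norm["subset_id"].isin(excluded)])

print("\nmost variable subsets (between-individual variance, mean-normalized):")
cols = ["subset_id", "var_between", "var_within", "prop_within"]
print(kept.nlargest(5, "var_between")[cols].to_string(index=False,
                                                      float_format="%.3f"))
print(f"\nmedian prop_within = {kept['prop_within'].median():.2f} "
      "-> most variance is stable individual identity, not fluctuation")

fit = regress_within_on_between(kept)
print(f"\nOLS var_within ~ var_between across {fit.n_subsets} subsets: "
      f"adj R^2 = {fit.adjusted_r_squared:.2f}, t = {fit.t_value:.1f} "
      "(subsets that differ most between people also fluctuate most)")
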