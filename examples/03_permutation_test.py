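"""Is between-individual variance larger than within-individual variance?

Permutation test per subset: shuffle individual labels, recompute
T = var_between - var_within, one-sided add-one p-value.
"""

import cytomevar as cv
from cytomevar.resampling import permutation_test_variance
from cytomevar.variance import mean_normalize

config = cv.GeneratorConfig(seed=7)
obs, _ = cv.generate_cohort(config)
norm = mean_normalize(obs)

for subset in ("cd4_memory", "plasmablast"):
    res = permutation_test_variance(norm, subset, n_permutations=9999, seed=1)
    print(f"{subset:12s} T = {res.observed_stat:+.4f} "
          f"(null {res.null_mean:+.4f} +/- {res.null_sd:.4f}), "
          f"p = {res.p_value:.4f}")
print("\nsmall p: individuals keep distinct baselines for that subset; "
      "the null destroys individual identity while preserving visit counts")
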