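import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import cytomevar as cv
from cytomevar.variance import (MeanNormalizationError, descriptive_variances,
                                detect_outlier_subsets,
                                fit_variance_components, mean_normalize,
                                regress_within_on_between)

from conftest import make_obs


def anova_components(y: np.ndarray) -> tuple[float, float]:
    """Balanced one-way ANOVA method-of-moments oracle (rows = individuals)."""
    n = y.shape[1]
    msw = y.var(axis=1, ddof=1).mean()
    msb = n * y.mean(axis=1).var(ddof=1)
    return max((msb - msw) / n, 0.0), msw


class TestMeanNormalize:
    def test_constant_subset_maps_to_ones(self):
        obs = make_obs({"A": [5.0], "B": [5.0], "C": [5.0]})
        out = mean_normalize(obs)
        assert (out["value"] == 1.0).all()

    def test_hand_example_values_and_variance(self):
        obs = make_obs({"A": [1.0], "B": [2.0], "C": [3.0]})
        out = mean_normalize(obs)
        assert out["value"].tolist() == [0.5, 1.0, 1.5]
        assert out["value"].var(ddof=1) == pytest.approx(0.25)

    def test_scale_invariance_across_subsets(self):
        lo = make_obs({"A": [0.1], "B": [0.2], "C": [0.3]}, subset_id="lo")
        hi = make_obs({"A": [50.0], "B": [100.0], "C": [150.0]}, subset_id="hi")
        out = mean_normalize(pd.concat([lo, hi], ignore_index=True))
        v = out.groupby("subset_id")["value"].var(ddof=1)
        assert v["lo"] == pytest.approx(v["hi"])

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(1e-3, 1e3),
           vals=st.lists(st.floats(0.01, 0.09), min_size=3, max_size=8))
    def test_scale_invariance_property(self, scale, vals):
        base = make_obs({f"I{k}": [v] for k, v in enumerate(vals)})
        scaled = base.assign(frequency_pct=base["frequency_pct"] * scale)
        v0 = mean_normalize(base)["value"].var(ddof=1)
        v1 = mean_normalize(scaled)["value"].var(ddof=1)
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_zero_mean_subset_errors(self):
        obs = make_obs({"A": [0.0], "B": [0.0]})
        with pytest.raises(MeanNormalizationError, match="s1"):
            mean_normalize(obs)


class TestDescriptiveVariances:
    def test_hand_oracle_two_individuals(self, tiny_obs):
        norm = tiny_obs.rename(columns={}).assign(value=tiny_obs["frequency_pct"])
        out = descriptive_variances(norm)
        row = out.iloc[0]
        # per-individual vars (2, 2) -> mean 2; means (2, 6) -> variance 8
        assert row["var_within"] == pytest.approx(2.0)
        assert row["var_between"] == pytest.approx(8.0)

    def test_pure_between_structure(self):
        obs = make_obs({"A": [1.0, 1.0], "B": [2.0, 2.0], "C": [3.0, 3.0]})
        out = descriptive_variances(obs.assign(value=obs["frequency_pct"]))
        assert out.loc[0, "var_within"] == 0.0
        assert out.loc[0, "var_between"] > 0.0

    def test_visit_order_is_exchangeable(self, small_cohort):
        obs, _ = small_cohort
        norm = mean_normalize(obs)
        shuffled = norm.sample(frac=1.0, random_state=1)
        a = descriptive_variances(norm)
        b = descriptive_variances(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_single_visit_individual_counts_only_between(self):
        obs = make_obs({"A": [1.0, 3.0], "B": [5.0, 7.0], "C": [4.0]})
        out = descriptive_variances(obs.assign(value=obs["frequency_pct"]))
        # C contributes its single value to the between spread only
        assert out.loc[0, "var_within"] == pytest.approx(2.0)
        assert out.loc[0, "var_between"] == pytest.approx(
            np.var([2.0, 6.0, 4.0], ddof=1))


class TestVarianceComponents:
    def test_degenerate_all_equal(self):
        obs = make_obs({"A": [2.0, 2.0], "B": [2.0, 2.0], "C": [2.0, 2.0]})
        vc = fit_variance_components(obs.assign(value=obs["frequency_pct"]))
        assert vc.sigma2_b == 0.0 and vc.sigma2_w == 0.0
        assert vc.degenerate and np.isnan(vc.prop_within)

    def test_balanced_toy_matches_anova_closed_form(self):
        obs = make_obs({"A": [1.0, 3.0], "B": [5.0, 7.0], "C": [9.0, 11.0]})
        vc = fit_variance_components(obs.assign(value=obs["frequency_pct"]))
        # MSW = 2, MSB = 32 -> sigma2_w = 2, sigma2_b = (32-2)/2 = 15
        assert vc.sigma2_w == pytest.approx(2.0, abs=1e-6)
        assert vc.sigma2_b == pytest.approx(15.0, abs=1e-6)
        assert vc.prop_within == pytest.approx(2.0 / 17.0, abs=1e-6)

    def test_boundary_truncation_flagged(self):
        # within-noise dominates: between component hits the 0 boundary
        rng = np.random.default_rng(3)
        obs = make_obs({f"I{k}": (rng.normal(10, 1, 4) * 0 + 10
                                  + np.array([-1, 1, -1, 1]) * (k % 2 + 1)).tolist()
                        for k in range(6)})
        vc = fit_variance_components(obs.assign(value=obs["frequency_pct"]))
        assert vc.sigma2_b == 0.0
        assert vc.truncated

    def test_matches_mixedlm_reml_on_unbalanced_data(self):
        rng = np.random.default_rng(11)
        sizes = [2, 4, 3, 5, 2, 4, 3, 4]
        vals = {f"I{k}": (rng.normal(0, 0.5, s) + rng.normal(0, 1)).tolist()
                for k, s in enumerate(sizes)}
        obs = make_obs({k: [v + 10 for v in vs] for k, vs in vals.items()})
        vc = fit_variance_components(obs.assign(value=obs["frequency_pct"]))
        y = obs["frequency_pct"].to_numpy()
        groups = obs["individual_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=True)
        assert vc.sigma2_b == pytest.approx(float(np.asarray(res.cov_re)[0, 0]),
                                            abs=1e-3)
        assert vc.sigma2_w == pytest.approx(float(res.scale), abs=1e-3)

    def test_recovers_generator_truth_at_large_n(self):
        spec = cv.SubsetSpec("s", 5.0, 0.3, 0.2, 0.0)
        cfg = cv.GeneratorConfig(n_individuals=600, n_visits=4, subsets=[spec],
                                 seed=17)
        obs, _ = cv.generate_cohort(cfg)
        vc = fit_variance_components(mean_normalize(obs))
        # on mean-normalized values: between = e^{s_b^2}-1, within =
        # s_w^2 e^{-s_b^2} (value = (e^b + e)/E[e^b])
        assert vc.sigma2_b == pytest.approx(np.expm1(0.09), rel=0.15)
        assert vc.sigma2_w == pytest.approx(0.04 * np.exp(-0.09), rel=0.15)


class TestOutlierDetection:
    def test_far_out_value_flagged(self):
        summary = pd.DataFrame({
            "subset_id": list("abcde"),
            "var_technical": [1.0, 1.0, 1.0, 1.0, 100.0]})
        out = detect_outlier_subsets(summary)
        assert out.loc[out["flagged"], "subset_id"].tolist() == ["e"]

    def test_all_equal_nothing_flagged(self):
        summary = pd.DataFrame({"subset_id": list("abcde"),
                                "var_technical": [2.0] * 5})
        assert not detect_outlier_subsets(summary)["flagged"].any()

    def test_engineered_noisy_subset_flagged_from_generator(self):
        subsets = [cv.SubsetSpec(f"s{k}", 5.0, 0.2, 0.1) for k in range(7)]
        subsets.append(cv.SubsetSpec("noisy", 5.0, 0.2, 0.1,
                                     technical_cv_multiplier=50.0))
        cfg = cv.GeneratorConfig(subsets=subsets, technical_cv=0.03,
                                 n_replicate_runs=30, seed=23)
        reps = mean_normalize(cv.generate_replicates(cfg))
        obs, _ = cv.generate_cohort(cfg)
        summary = descriptive_variances(mean_normalize(obs), reps)
        out = detect_outlier_subsets(summary, "var_technical")
        assert out.loc[out["flagged"], "subset_id"].tolist() == ["noisy"]

    def test_needs_five_subsets(self):
        summary = pd.DataFrame({"subset_id": list("abc"),
                                "var_technical": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            detect_outlier_subsets(summary)


class TestRegression:
    def test_perfect_proportionality(self):
        summary = pd.DataFrame({
            "subset_id": list("abcdef"),
            "var_between": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "var_technical": np.nan})
        summary["var_within"] = 0.5 * summary["var_between"]
        rep = regress_within_on_between(summary)
        assert rep.adjusted_r_squared == pytest.approx(1.0)
        assert rep.slope == pytest.approx(0.5)

    def test_matches_normal_equations_oracle(self):
        x = np.array([0.2, 0.5, 1.1, 1.7, 2.3])
        y = np.array([0.1, 0.4, 0.5, 0.9, 1.0])
        summary = pd.DataFrame({"subset_id": list("abcde"), "var_between": x,
                                "var_within": y, "var_technical": np.nan})
        rep = regress_within_on_between(summary)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert rep.intercept == pytest.approx(beta[0], abs=1e-10)
        assert rep.slope == pytest.approx(beta[1], abs=1e-10)

    def test_collinear_covariates_rejected(self):
        summary = pd.DataFrame({
            "subset_id": list("abcdefg"),
            "var_between": np.arange(7, dtype=float),
            "var_within": np.arange(7, dtype=float) * 0.3 + 0.1})
        summary["var_technical"] = summary["var_between"]  # exact copy
        with pytest.raises(ValueError, match="collinear"):
            regress_within_on_between(summary, adjust_technical=True)
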