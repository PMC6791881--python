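import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

import cytomevar as cv
from cytomevar.multivariate import (correlation_matrix, correlation_network,
                                    fdr_adjust, group_comparison,
                                    pca_individuals)

from conftest import make_obs


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])

    def test_hand_step_up_examples(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])
        assert fdr_adjust([0.005, 0.04, 0.2]) == pytest.approx(
            [0.015, 0.06, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, p):
        q = fdr_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(ref, abs=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()

    def test_preserves_p_ordering(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 7.0)
        X = pd.DataFrame(np.outer(u, [1.0, 2.0, 3.0]),
                         index=[f"I{k}" for k in range(6)],
                         columns=list("abc"))
        res = pca_individuals(X, standardize=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_feature_eigenvalue_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.multivariate_normal(
            [0, 0], [[2.0, 0.8], [0.8, 1.0]], size=200), columns=["a", "b"])
        res = pca_individuals(X, standardize=False)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.to_numpy().T)))[::-1]
        assert res.explained_variance_ratio == pytest.approx(
            evals / evals.sum(), abs=1e-12)

    def test_matches_sklearn_and_reconstructs(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        res = pca_individuals(X, standardize=True)
        ref = PCA().fit(
            (X - X.mean()) / X.std(ddof=1)).explained_variance_ratio_
        assert res.explained_variance_ratio == pytest.approx(ref, abs=1e-10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        Xc = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        res = pca_individuals(X)
        L = res.loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_missing_cells_require_imputation_flag(self):
        X = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        X.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_individuals(X)
        res = pca_individuals(X + np.arange(5)[:, None], impute_mean=True)
        assert res.scores.shape == (5, 3)


class TestCorrelationMatrix:
    def _features(self, n=20, k=4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            columns=[f"s{j}" for j in range(k)])

    def test_duplicated_feature_perfect_rho(self):
        X = self._features()
        X["dup"] = X["s0"]
        cm = correlation_matrix(X)
        assert cm.rho.loc["s0", "dup"] == pytest.approx(1.0)
        assert cm.q.loc["s0", "dup"] == cm.q.to_numpy()[np.isfinite(
            cm.q.to_numpy())].min()

    def test_matches_scipy_spearman_oracle(self):
        X = self._features(n=12, k=5, seed=4)
        cm = correlation_matrix(X)
        rho_ref, p_ref = stats.spearmanr(X.to_numpy(), axis=0)
        assert np.allclose(cm.rho.to_numpy(), rho_ref, atol=1e-12)
        iu = np.triu_indices(5, 1)
        assert cm.p.to_numpy()[iu] == pytest.approx(p_ref[iu], abs=1e-9)

    def test_q_symmetric_and_over_upper_triangle(self):
        X = self._features(k=6)
        cm = correlation_matrix(X)
        Q = cm.q.to_numpy()
        assert np.allclose(Q, Q.T, equal_nan=True)
        iu = np.triu_indices(6, 1)
        assert cm.q.to_numpy()[iu] == pytest.approx(
            fdr_adjust(cm.p.to_numpy()[iu]))

    def test_constant_feature_flagged(self):
        X = self._features()
        X["flat"] = 2.0
        cm = correlation_matrix(X)
        assert cm.undefined == ["flat"]
        assert cm.rho["flat"].drop("flat").isna().all()


class TestNetwork:
    def _cm(self):
        X = pd.DataFrame({
            "a": [1.0, 2, 3, 4, 5, 6],
            "b": [1.1, 2.2, 2.9, 4.3, 6.1, 5.2],     # tracks a, one swap
            "c": [6.0, 5, 4, 2, 3, 1],               # anti-tracks a, one swap
            "d": [0.4, 2.8, 0.7, 2.1, 1.8, 0.2]})    # unrelated
        return correlation_matrix(X)

    def test_loose_thresholds_give_complete_graph(self):
        edges = correlation_network(self._cm(), q_threshold=1.1,
                                    rho_threshold=0.0)
        assert len(edges) == 6  # C(4,2)

    def test_q_below_minimum_attainable_gives_empty_list(self):
        cm = self._cm()
        q_min = np.nanmin(cm.q.to_numpy())
        assert q_min > 0
        edges = correlation_network(cm, q_threshold=q_min / 2)
        assert edges.empty

    def test_filter_matches_direct_selection(self):
        cm = self._cm()
        edges = correlation_network(cm, q_threshold=0.05, rho_threshold=0.5)
        # oracle: direct pandas filter on the long-form matrix
        lf = cm.long_form()
        expected = lf[(lf["q"] < 0.05) & (lf["rho"].abs() >= 0.5)]
        got = {tuple(sorted((r.subset_a, r.subset_b)))
               for r in edges.itertuples()}
        assert got == {tuple(sorted((r.subset_a, r.subset_b)))
                       for r in expected.itertuples()}
        assert ("a", "b") in got and ("a", "c") in got
        assert set(edges["sign"]) == {1, -1}

    def test_same_parent_edges_dropped_with_catalog(self):
        cm = self._cm()
        catalog = pd.DataFrame(
            [("a", "A", "root", ""), ("b", "B", "root", ""),
             ("c", "C", "other", ""), ("d", "D", "other", "")],
            columns=["subset_id", "label", "parent_gate_id", "marker_text"])
        edges = correlation_network(cm, 0.05, 0.5, catalog=catalog,
                                    drop_same_parent=True)
        pairs = {tuple(sorted((r.subset_a, r.subset_b)))
                 for r in edges.itertuples()}
        assert ("a", "b") not in pairs and ("a", "c") in pairs


class TestGroupComparison:
    def _obs(self, x_vals, y_vals):
        obs = make_obs({f"M{k}": [v] for k, v in enumerate(x_vals)})
        fem = make_obs({f"F{k}": [v] for k, v in enumerate(y_vals)})
        fem["sex"] = "F"
        obs["sex"] = "M"
        return pd.concat([obs, fem], ignore_index=True)

    def test_exact_enumeration_toy(self):
        out = group_comparison(self._obs([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        # fully separated groups: two-sided exact p = 2/20
        assert out.loc[0, "p_value"] == pytest.approx(2.0 / 20.0)
        assert out.loc[0, "method"] == "exact"

    def test_bonferroni_clipped_at_one(self):
        obs = pd.concat([
            self._obs([1.0, 3.0, 2.0], [2.5, 1.5, 3.5]).assign(subset_id=f"s{k}")
            for k in range(4)], ignore_index=True)
        out = group_comparison(obs)
        assert (out["p_bonferroni"] <= 1.0).all()
        assert out["p_bonferroni"].max() == 1.0

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="needs >=2"):
            group_comparison(self._obs([1.0, 2.0], [3.0]))

    def test_collapses_visits_before_testing(self):
        obs = self._obs([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        doubled = pd.concat([obs, obs.assign(visit_index=2)],
                            ignore_index=True)
        a = group_comparison(obs)
        b = group_comparison(doubled)
        assert a.loc[0, "p_value"] == b.loc[0, "p_value"]
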