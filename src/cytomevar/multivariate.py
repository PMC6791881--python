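"""Multivariate structure: PCA of individuals, correlation networks, group tests.

Individuals are represented by feature vectors built from the fluctuation
summary — per-subset baselines (mean z-score), per-subset fluctuations
(variance of z-scores), or both concatenated.  PCA asks whether individuals
form discrete immunotype clusters; the correlation matrix asks which subsets
co-vary across individuals, with Benjamini-Hochberg FDR control over the
upper triangle; the network view keeps only edges passing q and |rho|
thresholds.  Sex differences are tested per subset by the Mann-Whitney
rank-sum test with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, clipped at 1.  NaN entries are
    ignored (excluded from m) and propagate as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = q
    out[mask] = restored
    return out


@dataclass
class PcaResult:
    scores: pd.DataFrame                 # individuals x components
    loadings: pd.DataFrame               # features x components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def feature_matrix(fluct: pd.DataFrame, what: str = "both") -> pd.DataFrame:
    """Individuals x features matrix from a fluctuation summary.

    ``what`` selects ``baseline`` (mean z-scores), ``fluctuation`` (variance
    of z-scores) or ``both`` (columns suffixed ``:baseline``/``:fluct``).
    """
    pieces = []
    if what in ("baseline", "both"):
        wide = fluct.pivot(index="individual_id", columns="subset_id",
                           values="baseline_z_mean")
        pieces.append(wide.add_suffix(":baseline") if what == "both" else wide)
    if what in ("fluctuation", "both"):
        wide = fluct.pivot(index="individual_id", columns="subset_id",
                           values="fluctuation_z_var")
        pieces.append(wide.add_suffix(":fluct") if what == "both" else wide)
    if not pieces:
        raise ValueError(f"unknown feature kind {what!r}")
    return pd.concat(pieces, axis=1)


def pca_individuals(features: pd.DataFrame, standardize: bool = True,
                    impute_mean: bool = False) -> PcaResult:
    """PCA of individuals via SVD of the centered (optionally unit-scaled)
    feature matrix.

    Component signs are fixed so each component's largest-magnitude loading
    is positive.  Explained-variance ratios come from the squared singular
    values and sum to 1 over all components.
    """
    if features.shape[0] < 3 or features.shape[1] < 2:
        raise ValueError("need >=3 individuals and >=2 features")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        if not impute_mean:
            rows, cols = np.where(np.isnan(X))
            cells = [(features.index[r], features.columns[c])
                     for r, c in zip(rows[:10], cols[:10])]
            raise ValueError(f"missing cells (pass impute_mean=True): {cells}")
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0                     # constant columns stay zero
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(len(S)):                   # deterministic sign convention
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    ss = S**2
    evr = ss / ss.sum() if ss.sum() > 0 else np.zeros_like(ss)
    comp = [f"PC{k + 1}" for k in range(len(S))]
    return PcaResult(
        scores=pd.DataFrame(U * S, index=features.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=features.columns, columns=comp),
        explained_variance_ratio=evr,
    )


@dataclass
class CorrelationMatrixResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: int
    undefined: list[str] = field(default_factory=list)  # constant features

    def long_form(self) -> pd.DataFrame:
        """Upper-triangle cells as (subset_a, subset_b, rho, p, q) rows."""
        cols = self.rho.columns
        rows = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                rows.append((cols[i], cols[j], self.rho.iat[i, j],
                             self.p.iat[i, j], self.q.iat[i, j]))
        return pd.DataFrame(rows, columns=["subset_a", "subset_b", "rho", "p", "q"])


def correlation_matrix(features: pd.DataFrame) -> CorrelationMatrixResult:
    """Pairwise Spearman correlations across individuals with BH-FDR q-values.

    The q-values are computed over the strict upper triangle only (m =
    k(k-1)/2 tests) and mirrored.  Constant features yield NaN rows/columns
    and are listed in ``undefined``.
    """
    n, k = features.shape
    if n < 5:
        raise ValueError("need >=5 individuals")
    X = features.to_numpy(dtype=float)
    undefined = [str(c) for c, v in zip(features.columns, X.T) if np.ptp(v) == 0]
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = ranks.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        Z = (ranks - ranks.mean(axis=0)) / sd
        rho = (Z.T @ Z) / (n - 1)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    iu = np.triu_indices(k, 1)
    q_flat = fdr_adjust(p[iu])
    q = np.full((k, k), np.nan)
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat

    cols = features.columns
    as_df = lambda M: pd.DataFrame(M, index=cols, columns=cols)
    return CorrelationMatrixResult(as_df(rho), as_df(p), as_df(q), n, undefined)


def correlation_network(cm: CorrelationMatrixResult, q_threshold: float = 0.05,
                        rho_threshold: float = 0.0,
                        catalog: pd.DataFrame | None = None,
                        drop_same_parent: bool = False) -> pd.DataFrame:
    """Edge list of subset pairs with q < ``q_threshold`` and |rho| >=
    ``rho_threshold``.

    With ``drop_same_parent`` (requires a catalog), pairs sharing a parent
    gate are removed: their negative correlations are compositional
    artifacts of frequencies summing within the parent.
    """
    edges = cm.long_form()
    keep = (edges["q"] < q_threshold) & (edges["rho"].abs() >= rho_threshold)
    edges = edges.loc[keep.fillna(False)].copy()
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    if drop_same_parent:
        if catalog is None:
            raise ValueError("drop_same_parent requires a catalog")
        parent = dict(zip(catalog["subset_id"], catalog["parent_gate_id"]))
        base = lambda s: str(s).split(":")[0]
        same = edges.apply(lambda r: parent.get(base(r["subset_a"]))
                           == parent.get(base(r["subset_b"])), axis=1)
        edges = edges.loc[~same]
    return edges.reset_index(drop=True)


def group_comparison(obs: pd.DataFrame, group_field: str = "sex",
                     groups: tuple[str, str] = ("M", "F")) -> pd.DataFrame:
    """Per-subset two-sided Mann-Whitney test between two groups of
    individuals, Bonferroni-adjusted.

    Each individual is first collapsed to their mean frequency over visits.
    The exact null distribution is used for combined n <= 20 without ties,
    the tie-corrected normal approximation otherwise.
    """
    per_ind = (obs.groupby(["subset_id", "individual_id"])
               .agg(value=("frequency_pct", "mean"), group=(group_field, "first"))
               .reset_index())
    rows = []
    for sid, grp in per_ind.groupby("subset_id"):
        x = grp.loc[grp["group"] == groups[0], "value"].to_numpy()
        y = grp.loc[grp["group"] == groups[1], "value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"{sid}: each group needs >=2 members "
                             f"({groups[0]}: {len(x)}, {groups[1]}: {len(y)})")
        combined = np.concatenate([x, y])
        ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (len(combined) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((sid, float(res.statistic), float(res.pvalue),
                     len(x), len(y), method))
    out = pd.DataFrame(rows, columns=["subset_id", "statistic", "p_value",
                                      f"n_{groups[0]}", f"n_{groups[1]}",
                                      "method"])
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * len(out))
    return out
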