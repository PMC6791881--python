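"""Between/within/technical variance of subset frequencies.

Frequencies of different subsets live on wildly different scales, so every
variance here is computed on *mean-normalized* values (each observation
divided by the subset's grand mean), which makes variances comparable across
subsets.  Three descriptive quantities are computed per subset:

``var_between``
    sample variance across individuals of the per-individual mean;
``var_within``
    unweighted mean across individuals (with >=2 visits) of the
    per-individual sample variance over visits;
``var_technical``
    sample variance across staining runs of the mean-normalized control
    sample.

On top of the descriptive quantities, a one-way random-intercept model
``y_ij = mu + b_i + e_ij`` is fitted by REML to partition total variance into
a between-individual component ``sigma2_b`` and a within-individual
(residual) component ``sigma2_w``; ``prop_within = sigma2_w /
(sigma2_b + sigma2_w)`` is the fraction of population variance attributable
to within-individual fluctuation.

All sample variances use the n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

VARIANCE_SUMMARY_COLUMNS = [
    "subset_id", "mean_raw", "var_between", "var_within", "var_technical",
    "sigma2_b", "sigma2_w", "prop_within", "n_individuals",
    "mean_visits_per_individual",
]


class MeanNormalizationError(ValueError):
    """A subset's grand mean is zero (or it has too few observations)."""


class ConvergenceError(RuntimeError):
    """The mixed-model fit failed to converge."""


def mean_normalize(table: pd.DataFrame, value_col: str = "frequency_pct",
                   out_col: str = "value") -> pd.DataFrame:
    """Divide each observation by its subset's grand mean.

    Works on any table carrying ``subset_id`` and ``value_col`` (longitudinal
    observations or technical replicates alike).  The normalized values of
    every subset average exactly 1, so their variances are comparable across
    subsets with very different population sizes.
    """
    counts = table.groupby("subset_id")[value_col].size()
    few = counts.index[counts < 2].tolist()
    if few:
        raise MeanNormalizationError(f"subset(s) with <2 observations: {few}")
    means = table.groupby("subset_id")[value_col].transform("mean")
    zero = means == 0
    if zero.any():
        bad = sorted(table.loc[zero, "subset_id"].unique())
        raise MeanNormalizationError(f"subset(s) with zero mean: {bad}")
    out = table.copy()
    out[out_col] = table[value_col] / means
    return out


def descriptive_variances(norm: pd.DataFrame,
                          norm_replicates: pd.DataFrame | None = None,
                          value_col: str = "value") -> pd.DataFrame:
    """Per-subset descriptive variance summary on mean-normalized data.

    Individuals with a single visit contribute to ``var_between`` (their one
    value is their mean) but not to ``var_within``; if no individual has >=2
    visits the within variance is reported as NaN.
    """
    per_ind = norm.groupby(["subset_id", "individual_id"])[value_col]
    ind_mean = per_ind.mean()
    ind_var = per_ind.var(ddof=1)
    ind_n = per_ind.size()
    n_ind = ind_mean.groupby(level="subset_id").size()
    if (n_ind < 2).any():
        bad = n_ind.index[n_ind < 2].tolist()
        raise ValueError(f"need >=2 individuals per subset; offending: {bad}")

    var_between = ind_mean.groupby(level="subset_id").var(ddof=1)
    eligible = ind_var[ind_n >= 2]
    var_within = eligible.groupby(level="subset_id").mean()

    summary = pd.DataFrame({
        "subset_id": var_between.index,
        "mean_raw": norm.groupby("subset_id")["frequency_pct"].mean().reindex(
            var_between.index).to_numpy() if "frequency_pct" in norm else np.nan,
        "var_between": var_between.to_numpy(),
        "var_within": var_within.reindex(var_between.index).to_numpy(),
        "n_individuals": n_ind.reindex(var_between.index).to_numpy(),
        "mean_visits_per_individual": ind_n.groupby(level="subset_id").mean()
            .reindex(var_between.index).to_numpy(),
    })
    if norm_replicates is not None:
        tech = norm_replicates.groupby("subset_id")[value_col].var(ddof=1)
        summary["var_technical"] = tech.reindex(summary["subset_id"]).to_numpy()
    else:
        summary["var_technical"] = np.nan
    summary["sigma2_b"] = np.nan
    summary["sigma2_w"] = np.nan
    summary["prop_within"] = np.nan
    return summary[VARIANCE_SUMMARY_COLUMNS].reset_index(drop=True)


@dataclass
class VarianceComponents:
    """REML estimates of the one-way random-intercept partition."""

    sigma2_b: float
    sigma2_w: float
    prop_within: float          # NaN when both components are 0
    n_individuals: int
    n_observations: int
    truncated: bool             # between component hit the 0 boundary
    degenerate: bool = False    # all observations equal

    @property
    def prop_between(self) -> float:
        return 1.0 - self.prop_within


def _neg2_reml(lam: float, n_i: np.ndarray, ybar: np.ndarray,
               ssw: float, n_total: int) -> float:
    """-2 x restricted log-likelihood, profiled over mu and sigma2_w.

    ``lam`` is the variance ratio sigma2_b / sigma2_w; ``n_i`` the per-group
    sizes, ``ybar`` the group means and ``ssw`` the pooled within-group sum
    of squares.  Constants independent of ``lam`` are dropped.
    """
    w = n_i / (1.0 + n_i * lam)
    mu = float(w @ ybar) / w.sum()
    q = ssw + float(w @ (ybar - mu) ** 2)
    sigma2_w = q / (n_total - 1)
    return ((n_total - 1) * np.log(sigma2_w)
            + float(np.log1p(n_i * lam).sum()) + np.log(w.sum()))


def fit_variance_components(norm: pd.DataFrame, subset_id: str | None = None,
                            value_col: str = "value") -> VarianceComponents:
    """Fit ``y_ij = mu + b_i + e_ij`` (random intercept per individual) by REML.

    The restricted likelihood of the one-way random-intercept model is
    profiled over the grand mean and the residual variance, leaving a
    one-dimensional search over the variance ratio; on balanced data the
    result coincides with the ANOVA method-of-moments estimator whenever the
    latter is nonnegative.  Boundary estimates (between-component 0) are
    reported with ``truncated=True``.
    """
    df = norm if subset_id is None else norm[norm["subset_id"] == subset_id]
    y = df[value_col].to_numpy(dtype=float)
    groups = df["individual_id"].to_numpy()
    n_ind = len(np.unique(groups))
    if n_ind < 3:
        raise ValueError("need >=3 individuals to fit variance components")
    counts = pd.Series(y).groupby(groups).size().to_numpy()
    if counts.max() < 2:
        raise ValueError("need >=2 visits for at least some individuals")
    if np.ptp(y) == 0.0:
        return VarianceComponents(0.0, 0.0, float("nan"), n_ind, len(y),
                                  truncated=False, degenerate=True)

    ser = pd.Series(y).groupby(groups)
    ybar = ser.mean().to_numpy()
    ssw = float(((y - ser.transform("mean").to_numpy()) ** 2).sum())
    n_total = len(y)
    obj = lambda lam: _neg2_reml(lam, counts.astype(float), ybar, ssw, n_total)

    # coarse bracket on a log grid (plus the boundary), then Brent refine
    grid = np.concatenate([[0.0], np.logspace(-8.0, 8.0, 65)])
    vals = np.array([obj(l) for l in grid])
    if not np.isfinite(vals).all():
        raise ConvergenceError(
            f"REML criterion not finite for subset {subset_id!r}")
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-13, "maxiter": 500})
    lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    if obj(0.0) <= obj(lam):
        lam = 0.0

    w = counts / (1.0 + counts * lam)
    mu = float(w @ ybar) / w.sum()
    q = ssw + float(w @ (ybar - mu) ** 2)
    sigma2_w = q / (n_total - 1)
    sigma2_b = lam * sigma2_w
    truncated = lam <= 1e-12
    if truncated:
        sigma2_b = 0.0
    total = sigma2_b + sigma2_w
    prop_within = sigma2_w / total if total > 0 else float("nan")
    return VarianceComponents(sigma2_b, sigma2_w, prop_within, n_ind, len(y),
                              truncated=truncated)


def add_variance_components(summary: pd.DataFrame, norm: pd.DataFrame,
                            subset_ids=None) -> pd.DataFrame:
    """Fill ``sigma2_b``/``sigma2_w``/``prop_within`` in a variance summary."""
    out = summary.set_index("subset_id")
    targets = out.index if subset_ids is None else list(subset_ids)
    for sid in targets:
        vc = fit_variance_components(norm, sid)
        out.loc[sid, ["sigma2_b", "sigma2_w", "prop_within"]] = (
            vc.sigma2_b, vc.sigma2_w, vc.prop_within)
    return out.reset_index()


def detect_outlier_subsets(summary: pd.DataFrame, field: str = "var_technical",
                           fence_k: float = 3.0) -> pd.DataFrame:
    """Flag subsets whose ``field`` exceeds the Tukey far-out fence.

    The fence is Q3 + ``fence_k``·IQR with type-7 (linear interpolation)
    quartiles over the non-missing values.  Flagged subsets should be dropped
    from downstream stages but kept in reports.
    """
    if len(summary) < 5:
        raise ValueError("need >=5 subsets for outlier detection")
    vals = summary[field].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError(f"no finite values in field {field!r}")
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    fence = q3 + fence_k * (q3 - q1)
    flagged = np.isfinite(vals) & (vals > fence)
    return pd.DataFrame({
        "subset_id": summary["subset_id"],
        "field": field,
        "value": vals,
        "fence": fence,
        "flagged": flagged,
    })


@dataclass
class RegressionReport:
    """OLS of within-individual on between-individual variance across subsets."""

    slope: float
    intercept: float
    adjusted_r_squared: float
    t_value: float              # t statistic of the var_between coefficient
    p_value: float
    covariates: list[str]
    n_subsets: int


def regress_within_on_between(summary: pd.DataFrame,
                              adjust_technical: bool = False) -> RegressionReport:
    """Regress per-subset within-individual variance on between-individual
    variance (optionally adjusting for technical variance as a covariate).

    A strong fit indicates that subsets fluctuating a lot within people are
    the same subsets that differ a lot between people.
    """
    covars = ["var_between"] + (["var_technical"] if adjust_technical else [])
    cols = ["var_within"] + covars
    df = summary[cols].dropna()
    if len(df) < len(covars) + 3:
        raise ValueError(f"need >={len(covars) + 3} complete subsets, have {len(df)}")
    X = sm.add_constant(df[covars])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear covariates in variance regression")
    res = sm.OLS(df["var_within"], X).fit()
    return RegressionReport(
        slope=float(res.params["var_between"]),
        intercept=float(res.params["const"]),
        adjusted_r_squared=float(res.rsquared_adj),
        t_value=float(res.tvalues["var_between"]),
        p_value=float(res.pvalues["var_between"]),
        covariates=covars,
        n_subsets=int(len(df)),
    )
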