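"""Baseline vs fluctuation analysis on z-scored subset frequencies.

Each subset's observations are z-scored against the subset's cohort mean and
SD, which puts all subsets on a common scale.  Per individual and subset the
mean of the z-scores is the *baseline* (where the individual sits in the
population) and the sample variance of the z-scores is the *fluctuation*
(how much they move between visits).

A positive Spearman correlation between baseline and fluctuation across
individuals is the signature of an environmentally responsive subset:
upward fluctuation in response to exposures pushes the average up, so people
sitting high are also the people moving most.  Subsets whose baseline is set
independently of short-term environment show no such coupling.

``rank_concordance`` then asks whether the subsets with the strongest
coupling are also the subsets with the largest between-individual variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FLUCTUATION_COLUMNS = ["individual_id", "subset_id", "baseline_z_mean",
                       "fluctuation_z_var", "n_visits_used"]


class ZeroSpreadError(ValueError):
    """A subset has zero SD and cannot be z-scored."""


def zscore_transform(obs: pd.DataFrame, value_col: str = "frequency_pct",
                     out_col: str = "z") -> pd.DataFrame:
    """z-score each subset over all individuals and visits (n-1 SD)."""
    grp = obs.groupby("subset_id")[value_col]
    counts = grp.size()
    few = counts.index[counts < 2].tolist()
    if few:
        raise ZeroSpreadError(f"subset(s) with <2 observations: {few}")
    sd = grp.transform("std")
    zero = sd == 0
    if zero.any():
        bad = sorted(obs.loc[zero, "subset_id"].unique())
        raise ZeroSpreadError(f"subset(s) with zero SD: {bad}")
    out = obs.copy()
    out[out_col] = (obs[value_col] - grp.transform("mean")) / sd
    return out


def individual_baseline_fluctuation(z: pd.DataFrame, z_col: str = "z"
                                    ) -> pd.DataFrame:
    """Per (individual, subset): mean and sample variance of z-scores.

    Individuals with a single visit get a baseline but a missing (NaN)
    fluctuation.
    """
    grp = z.groupby(["individual_id", "subset_id"])[z_col]
    out = pd.DataFrame({
        "baseline_z_mean": grp.mean(),
        "fluctuation_z_var": grp.var(ddof=1),
        "n_visits_used": grp.size(),
    }).reset_index()
    return out[FLUCTUATION_COLUMNS]


@dataclass
class MeanVarCorrelation:
    subset_id: str
    spearman_rho: float
    p_value: float
    n_individuals: int


def _pearson_on(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=-1))
    return (Yc @ xc) / denom


def spearman_with_p(x: np.ndarray, y: np.ndarray,
                    exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    For n >= ``exact_below`` the usual t-approximation is used; below that,
    the exact permutation distribution of the rank correlation is enumerated
    (all n! orderings), so the p-value is exact even with ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(_pearson_on(rx, ry[None, :])[0])
    if n >= exact_below:
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    perms = np.array(list(itertools.permutations(ry)))
    rhos = _pearson_on(rx, perms)
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def mean_variance_correlation(summ: pd.DataFrame, subset_id: str
                              ) -> MeanVarCorrelation:
    """Spearman correlation of baseline vs fluctuation across individuals,
    one subset.  Positive rho = environmentally responsive signature."""
    df = summ.loc[summ["subset_id"] == subset_id,
                  ["baseline_z_mean", "fluctuation_z_var"]].dropna()
    if len(df) < 5:
        raise ValueError(f"{subset_id}: need >=5 individuals with both "
                         f"statistics, have {len(df)}")
    rho, p = spearman_with_p(df["baseline_z_mean"].to_numpy(),
                             df["fluctuation_z_var"].to_numpy())
    return MeanVarCorrelation(subset_id, rho, p, len(df))


def mean_variance_correlation_all(summ: pd.DataFrame) -> pd.DataFrame:
    rows = [vars(mean_variance_correlation(summ, sid))
            for sid in sorted(summ["subset_id"].unique())]
    return pd.DataFrame(rows)


@dataclass
class RankConcordance:
    spearman_rho: float
    p_value: float
    n_subsets: int


def rank_concordance(var_summary: pd.DataFrame, mean_var: pd.DataFrame
                     ) -> RankConcordance:
    """Spearman correlation, across subsets, between the rank order of
    between-individual variance and the rank order of the mean-variance
    coupling coefficient."""
    a = set(var_summary["subset_id"])
    b = set(mean_var["subset_id"])
    if a != b:
        raise ValueError(f"subset sets differ: only in variance summary "
                         f"{sorted(a - b)}, only in correlations {sorted(b - a)}")
    merged = var_summary[["subset_id", "var_between"]].merge(
        mean_var[["subset_id", "spearman_rho"]], on="subset_id").dropna()
    rho, p = spearman_with_p(merged["var_between"].to_numpy(),
                             merged["spearman_rho"].to_numpy())
    return RankConcordance(rho, p, len(merged))
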