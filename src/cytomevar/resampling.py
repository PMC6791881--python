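"""Resampling tests: variance permutation test and sibling concordance.

Two bespoke procedures:

1.  Per subset, is between-individual variance larger than within-individual
    variance?  The statistic is ``T = var_between - var_within`` on
    mean-normalized values; the null is built by permuting individual labels
    across all observations (destroying individual identity, preserving the
    marginal distribution and each individual's visit count).

2.  Are siblings more alike than unrelated people?  Each cohort is z-scored
    per subset against its own mean/SD; the statistic is the mean absolute
    z-difference over all within-family sibling pairs, compared with the same
    number of unrelated pairs resampled from a single-visit reference cohort.

Both use the add-one convention ``p = (1 + #{null at least as extreme}) /
(B + 1)`` so p > 0 always; tiny inputs fall back to exhaustive enumeration
of all label assignments, in which case the p-value is the exact fraction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multivariate import fdr_adjust

logger = logging.getLogger(__name__)

_REL_TOL = 1e-12


@dataclass
class PermutationResult:
    subset_id: str
    observed_stat: float        # var_between - var_within
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int         # draws actually used (=count of assignments if exhaustive)
    seed: int
    exhaustive: bool = False


def _grouped_stat(V: np.ndarray, starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """T = var_between - var_within for each row of ``V``.

    Observations of one individual occupy a contiguous slice; ``starts`` and
    ``counts`` describe the slices.  Vectorized over rows (permutations).
    """
    V = np.atleast_2d(V)
    sums = np.add.reduceat(V, starts, axis=1)
    sqs = np.add.reduceat(V * V, starts, axis=1)
    means = sums / counts
    var_between = means.var(axis=1, ddof=1)
    multi = counts >= 2
    ss = np.clip(sqs[:, multi] - counts[multi] * means[:, multi] ** 2, 0.0, None)
    var_within = (ss / (counts[multi] - 1)).mean(axis=1)
    return var_between - var_within


def _assignment_count(counts: np.ndarray) -> int:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _exhaustive_rows(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """All distinct assignments of observations to labeled groups of the
    given sizes, as rows of rearranged values."""
    n = len(values)
    rows: list[np.ndarray] = []

    def recurse(remaining: tuple[int, ...], prefix: list[int], k: int):
        if k == len(counts):
            rows.append(values[np.array(prefix)])
            return
        for combo in itertools.combinations(remaining, int(counts[k])):
            left = tuple(i for i in remaining if i not in combo)
            recurse(left, prefix + list(combo), k + 1)

    recurse(tuple(range(n)), [], 0)
    return np.vstack(rows)


def permutation_test_variance(norm: pd.DataFrame, subset_id: str,
                              n_permutations: int = 9999, seed: int = 0,
                              value_col: str = "value") -> PermutationResult:
    """Permutation test of between- vs within-individual variance, one subset.

    One-sided: small p means between-individual variance exceeds
    within-individual variance by more than label-exchange can explain.
    When the number of distinct label assignments does not exceed
    ``n_permutations`` the null is enumerated exhaustively and the p-value
    is exact.
    """
    df = norm.loc[norm["subset_id"] == subset_id]
    df = df.sort_values(["individual_id", "visit_index"]
                        if "visit_index" in df else "individual_id")
    values = df[value_col].to_numpy(dtype=float)
    counts = df.groupby("individual_id", sort=True).size().to_numpy()
    if (counts >= 2).sum() < 1 or len(counts) < 3:
        raise ValueError(f"{subset_id}: need >=3 individuals, some with >=2 visits")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    t_obs = float(_grouped_stat(values, starts, counts)[0])
    tol = _REL_TOL * max(1.0, abs(t_obs))

    n_assign = _assignment_count(counts)
    if n_assign <= n_permutations:
        logger.info("%s: only %d distinct assignments; enumerating exhaustively",
                    subset_id, n_assign)
        rows = _exhaustive_rows(values, counts)
        t_null = _grouped_stat(rows, starts, counts)
        p = float(np.count_nonzero(t_null >= t_obs - tol)) / n_assign
        return PermutationResult(subset_id, t_obs, float(t_null.mean()),
                                 float(t_null.std(ddof=1)), p, n_assign, seed,
                                 exhaustive=True)

    rng = np.random.default_rng(seed)
    idx = rng.permuted(
        np.broadcast_to(np.arange(len(values)), (n_permutations, len(values))).copy(),
        axis=1)
    t_null = _grouped_stat(values[idx], starts, counts)
    p = (1.0 + np.count_nonzero(t_null >= t_obs - tol)) / (n_permutations + 1.0)
    return PermutationResult(subset_id, t_obs, float(t_null.mean()),
                             float(t_null.std(ddof=1)), float(p),
                             n_permutations, seed)


def permutation_test_all(norm: pd.DataFrame, n_permutations: int = 999,
                         seed: int = 0, value_col: str = "value") -> pd.DataFrame:
    """Run the variance permutation test for every subset, with BH q-values.

    Each subset gets an independent random stream derived from ``seed``.
    """
    rows = []
    for k, sid in enumerate(sorted(norm["subset_id"].unique())):
        sub_seed = int(np.random.default_rng([k, seed]).integers(2**31))
        res = permutation_test_variance(norm, sid, n_permutations, sub_seed,
                                        value_col)
        rows.append(vars(res))
    out = pd.DataFrame(rows)
    out["q_value"] = fdr_adjust(out["p_value"].to_numpy())
    return out


@dataclass
class PairDistanceResult:
    subset_id: str
    observed_mean_distance: float
    null_mean: float
    null_sd: float
    p_value: float
    n_pairs: int
    n_resamples: int
    seed: int
    n_reference: int = 0


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD; cannot z-score")
    return (values - values.mean()) / sd


def sibling_pairs(siblings: pd.DataFrame) -> list[tuple[str, str]]:
    """All within-family pairs; families with <2 members are dropped."""
    pairs = []
    for fam, grp in siblings.groupby("family_id"):
        members = sorted(grp["individual_id"].unique())
        if len(members) < 2:
            logger.warning("family %s has <2 members; excluded", fam)
            continue
        pairs.extend(itertools.combinations(members, 2))
    return pairs


def sibling_concordance_test(siblings: pd.DataFrame, reference: pd.DataFrame,
                             subset_id: str, n_resamples: int = 9999,
                             seed: int = 0, allow_overlap: bool = False
                             ) -> PairDistanceResult:
    """Test whether siblings are closer than unrelated pairs for one subset.

    ``reference`` must hold one observation per individual for the subset
    (e.g. the longitudinal cohort restricted to one visit; see
    :func:`reference_from_observations`).  Both cohorts are z-scored
    separately, which removes cohort-level location/scale (batch) differences.

    Null draws sample the same number of *disjoint* unrelated pairs without
    replacement from the reference cohort; if the reference is too small for
    disjoint pairs, ``allow_overlap=True`` samples pairs independently
    (each pair still two distinct individuals) instead of raising.
    One-sided: small p means siblings are unusually concordant.
    """
    sib = siblings.loc[siblings["subset_id"] == subset_id]
    ref = reference.loc[reference["subset_id"] == subset_id]
    if ref["individual_id"].duplicated().any():
        raise ValueError("reference must hold one observation per individual "
                         "(restrict it to a single visit)")
    pairs = sibling_pairs(sib)
    if len(pairs) < 5:
        raise ValueError(f"{subset_id}: need >=5 sibling pairs, have {len(pairs)}")

    z_sib = pd.Series(_zscore(sib["frequency_pct"].to_numpy(dtype=float)),
                      index=sib["individual_id"].to_numpy())
    z_ref = _zscore(ref["frequency_pct"].to_numpy(dtype=float))
    n_ref = len(z_ref)
    n_pairs = len(pairs)

    observed = float(np.mean([abs(z_sib[a] - z_sib[b]) for a, b in pairs]))

    rng = np.random.default_rng(seed)
    if 2 * n_pairs <= n_ref:
        perm = rng.permuted(
            np.broadcast_to(np.arange(n_ref), (n_resamples, n_ref)).copy(),
            axis=1)[:, : 2 * n_pairs]
        a, b = perm[:, 0::2], perm[:, 1::2]
    elif allow_overlap:
        logger.warning("%s: reference (%d) too small for %d disjoint pairs; "
                       "sampling pairs independently", subset_id, n_ref, n_pairs)
        a = rng.integers(0, n_ref, size=(n_resamples, n_pairs))
        b = rng.integers(0, n_ref - 1, size=(n_resamples, n_pairs))
        b = b + (b >= a)
    else:
        raise ValueError(
            f"{subset_id}: reference cohort ({n_ref}) cannot supply "
            f"{n_pairs} disjoint pairs; pass allow_overlap=True to sample "
            "overlapping pairs")
    null = np.abs(z_ref[a] - z_ref[b]).mean(axis=1)
    tol = _REL_TOL * max(1.0, abs(observed))
    p = (1.0 + np.count_nonzero(null <= observed + tol)) / (n_resamples + 1.0)
    return PairDistanceResult(subset_id, observed, float(null.mean()),
                              float(null.std(ddof=1)), float(p), n_pairs,
                              n_resamples, seed, n_reference=n_ref)


def reference_from_observations(obs: pd.DataFrame, visit_index: int = 1
                                ) -> pd.DataFrame:
    """Restrict a longitudinal table to one visit, for use as the unrelated
    reference cohort."""
    ref = obs.loc[obs["visit_index"] == visit_index]
    if ref.empty:
        raise ValueError(f"no observations at visit_index={visit_index}")
    return ref


def sibling_concordance_all(siblings: pd.DataFrame, reference: pd.DataFrame,
                            n_resamples: int = 999, seed: int = 0,
                            allow_overlap: bool = False) -> pd.DataFrame:
    """Sibling concordance test for every subset present in both cohorts,
    with BH q-values."""
    shared = sorted(set(siblings["subset_id"]) & set(reference["subset_id"]))
    rows = []
    for k, sid in enumerate(shared):
        sub_seed = int(np.random.default_rng([k, seed]).integers(2**31))
        res = sibling_concordance_test(siblings, reference, sid, n_resamples,
                                       sub_seed, allow_overlap=allow_overlap)
        rows.append(vars(res))
    out = pd.DataFrame(rows)
    out["q_value"] = fdr_adjust(out["p_value"].to_numpy())
    return out
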