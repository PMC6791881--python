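"""Long-format tables for immunophenotyping cohorts: schemas, validation, CSV I/O.

All analysis stages consume plain :class:`pandas.DataFrame` objects with the
fixed column layouts documented in the ``*_COLUMNS`` constants below.  Subset
frequencies are percentages of a parent gate and must lie in [0, 100].

Four tables exist:

observations
    one row per (individual, visit, subset) from the longitudinal cohort;
replicates
    one row per (staining run, subset) for the control sample run alongside
    each acquisition batch;
siblings
    one row per (individual, subset) from the family cohort;
catalog
    the gating hierarchy: each subset, its display label, its parent gate and
    a free-text marker definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOT_GATE = "live PBMC"

OBS_COLUMNS = [
    "individual_id",
    "visit_index",
    "collection_date",
    "sex",
    "age_years",
    "subset_id",
    "frequency_pct",
]
REPLICATE_COLUMNS = ["run_id", "subset_id", "frequency_pct"]
SIBLING_COLUMNS = [
    "family_id",
    "individual_id",
    "sex",
    "age_years",
    "subset_id",
    "frequency_pct",
]
CATALOG_COLUMNS = ["subset_id", "label", "parent_gate_id", "marker_text"]

SEX_VALUES = {"M", "F", "unknown"}


class SchemaError(ValueError):
    """The file/table does not have the documented column layout."""


class ValidationError(ValueError):
    """The table content violates an invariant (range, uniqueness, reference)."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, col: str, what: str, as_int: bool = False):
    try:
        vals = pd.to_numeric(df[col], errors="raise")
        if as_int:
            vals = vals.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{what}: column {col!r} is not numeric: {exc}") from exc
    df[col] = vals


def _bad_rows(df: pd.DataFrame, mask: pd.Series, what: str, reason: str,
              strict: bool) -> pd.DataFrame:
    """Reject (strict) or drop (lenient) the rows where ``mask`` is True."""
    if not mask.any():
        return df
    rows = df.index[mask].tolist()
    if strict:
        raise ValidationError(f"{what}: {reason} at row(s) {rows[:20]}"
                              + (" ..." if len(rows) > 20 else ""))
    logger.warning("%s: dropping %d row(s) (%s)", what, int(mask.sum()), reason)
    return df.loc[~mask]


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a subset catalog: unique ids, resolvable parents, acyclic."""
    _require_columns(catalog, CATALOG_COLUMNS, "catalog")
    cat = catalog.copy()
    dup = cat["subset_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"catalog: duplicate subset_id(s) {sorted(cat.loc[dup, 'subset_id'])}")
    known = set(cat["subset_id"])
    parent = dict(zip(cat["subset_id"], cat["parent_gate_id"]))
    bad = [s for s, p in parent.items() if p != ROOT_GATE and p not in known]
    if bad:
        missing = sorted({parent[s] for s in bad})
        raise ValidationError(
            f"catalog: unresolvable parent_gate_id {missing} for {sorted(bad)}")
    for start in parent:
        seen, node = set(), start
        while node != ROOT_GATE:
            if node in seen:
                raise ValidationError(f"catalog: cycle in parent relation at {node!r}")
            seen.add(node)
            node = parent[node]
    return cat


def _validate_frequencies(df, what, strict):
    mask = ~df["frequency_pct"].between(0.0, 100.0)
    return _bad_rows(df, mask, what, "frequency_pct outside [0, 100]", strict)


def _validate_subset_refs(df, catalog, what, strict):
    if catalog is None:
        return df
    known = set(catalog["subset_id"])
    mask = ~df["subset_id"].isin(known)
    return _bad_rows(df, mask, what, "subset_id not in catalog", strict)


def _validate_unique(df, keys, what, strict):
    mask = df.duplicated(subset=keys, keep=False)
    if mask.any():
        dups = df.loc[mask, keys].drop_duplicates().itertuples(index=False, name=None)
        reason = f"duplicate key(s) {list(dups)[:10]} for ({', '.join(keys)})"
        if strict:
            raise ValidationError(f"{what}: {reason}")
        first = df.duplicated(subset=keys, keep="first")
        df = _bad_rows(df, first, what, reason, strict)
    return df


def validate_observations(obs: pd.DataFrame, catalog: pd.DataFrame | None = None,
                          strict: bool = True) -> pd.DataFrame:
    """Validate a longitudinal observation table.

    In strict mode any invariant violation raises :class:`ValidationError`
    naming the offending rows; in lenient mode bad rows are dropped and the
    count logged.
    """
    what = "observations"
    _require_columns(obs, OBS_COLUMNS, what)
    df = obs.copy()
    _coerce_numeric(df, "frequency_pct", what)
    _coerce_numeric(df, "visit_index", what, as_int=True)
    _coerce_numeric(df, "age_years", what)
    df = _bad_rows(df, df["visit_index"] < 1, what, "visit_index must be >= 1", strict)
    df = _bad_rows(df, df["age_years"] < 0, what, "age_years must be >= 0", strict)
    df = _bad_rows(df, ~df["sex"].isin(SEX_VALUES), what,
                   f"sex must be one of {sorted(SEX_VALUES)}", strict)
    df = _validate_frequencies(df, what, strict)
    df = _validate_subset_refs(df, catalog, what, strict)
    df = _validate_unique(df, ["individual_id", "visit_index", "subset_id"], what, strict)
    return df.reset_index(drop=True)


def validate_replicates(reps: pd.DataFrame, catalog: pd.DataFrame | None = None,
                        strict: bool = True) -> pd.DataFrame:
    what = "replicates"
    _require_columns(reps, REPLICATE_COLUMNS, what)
    df = reps.copy()
    _coerce_numeric(df, "frequency_pct", what)
    df = _validate_frequencies(df, what, strict)
    df = _validate_subset_refs(df, catalog, what, strict)
    df = _validate_unique(df, ["run_id", "subset_id"], what, strict)
    return df.reset_index(drop=True)


def validate_siblings(sib: pd.DataFrame, catalog: pd.DataFrame | None = None,
                      strict: bool = True) -> pd.DataFrame:
    what = "siblings"
    _require_columns(sib, SIBLING_COLUMNS, what)
    df = sib.copy()
    _coerce_numeric(df, "frequency_pct", what)
    _coerce_numeric(df, "age_years", what)
    df = _bad_rows(df, ~df["sex"].isin(SEX_VALUES), what,
                   f"sex must be one of {sorted(SEX_VALUES)}", strict)
    df = _validate_frequencies(df, what, strict)
    df = _validate_subset_refs(df, catalog, what, strict)
    df = _validate_unique(df, ["individual_id", "subset_id"], what, strict)
    fam_sizes = df.groupby("family_id")["individual_id"].nunique()
    single = fam_sizes.index[fam_sizes < 2].tolist()
    if single:
        msg = f"family_id(s) with <2 distinct individuals: {single}"
        if strict:
            raise ValidationError(f"{what}: {msg}")
        logger.warning("%s: dropping %s", what, msg)
        df = df.loc[~df["family_id"].isin(single)]
    return df.reset_index(drop=True)


_STR_COLS = {"individual_id", "subset_id", "run_id", "family_id", "sex",
             "collection_date", "label", "parent_gate_id", "marker_text"}


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={c: str for c in _STR_COLS})
    if "collection_date" in df.columns:
        df["collection_date"] = df["collection_date"].replace("", pd.NA)
    return df


def read_observations(path, catalog: pd.DataFrame | None = None,
                      strict: bool = True) -> pd.DataFrame:
    """Read and validate an observations CSV (see :data:`OBS_COLUMNS`)."""
    return validate_observations(_read_csv(path), catalog=catalog, strict=strict)


def read_replicates(path, catalog=None, strict: bool = True) -> pd.DataFrame:
    return validate_replicates(_read_csv(path), catalog=catalog, strict=strict)


def read_siblings(path, catalog=None, strict: bool = True) -> pd.DataFrame:
    return validate_siblings(_read_csv(path), catalog=catalog, strict=strict)


def read_catalog(path) -> pd.DataFrame:
    return validate_catalog(_read_csv(path))


def write_table(table: pd.DataFrame, path) -> None:
    """Write any cohort table as UTF-8 CSV; optional fields serialize as ''.

    Values round-trip exactly: floats are written with ``repr`` precision and
    parse back bit-for-bit.
    """
    table.to_csv(path, index=False, na_rep="",
                 float_format=lambda x: repr(float(x)))


@dataclass
class CompletenessReport:
    """Visit counts per individual and grid coverage per subset."""

    visits_per_individual: pd.Series
    ineligible_individuals: list[str]            # <2 visits: no within-individual variance
    missing_cells: pd.DataFrame                  # individual_id, visit_index, subset_id
    subsets_with_missing: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.ineligible_individuals and self.missing_cells.empty


def completeness_report(obs: pd.DataFrame) -> CompletenessReport:
    """Report which individuals/subsets fall short of the full visit grid.

    The expected grid is the cross product of the observed individuals,
    observed visit indices and observed subsets.
    """
    visits = obs.groupby("individual_id")["visit_index"].nunique().sort_index()
    ineligible = visits.index[visits < 2].tolist()
    individuals = obs["individual_id"].unique()
    visit_idx = np.sort(obs["visit_index"].unique())
    subsets = obs["subset_id"].unique()
    grid = pd.MultiIndex.from_product(
        [individuals, visit_idx, subsets],
        names=["individual_id", "visit_index", "subset_id"])
    observed = pd.MultiIndex.from_frame(obs[["individual_id", "visit_index", "subset_id"]])
    missing = grid.difference(observed).to_frame(index=False)
    return CompletenessReport(
        visits_per_individual=visits,
        ineligible_individuals=ineligible,
        missing_cells=missing,
        subsets_with_missing=sorted(missing["subset_id"].unique()),
    )
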