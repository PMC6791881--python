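"""End-to-end driver chaining all analysis stages on real or synthetic inputs.

Stage order: validate -> mean-normalize -> descriptive variances -> outlier
exclusion -> variance components -> within~between regression -> permutation
tests -> z-scores -> baseline/fluctuation -> mean-variance coupling -> rank
concordance -> PCA -> correlation matrix/network -> sex comparison ->
sibling concordance.  Every intermediate table is written to the output
directory together with a machine-readable ``summary.json``; the bundle is
byte-identical for identical (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .fluctuation import (individual_baseline_fluctuation,
                          mean_variance_correlation_all, rank_concordance,
                          zscore_transform)
from .multivariate import (correlation_matrix, correlation_network,
                           feature_matrix, group_comparison, pca_individuals)
from .resampling import (permutation_test_all, reference_from_observations,
                         sibling_concordance_all)
from .simulate import (GeneratorConfig, catalog_frame, generate_cohort,
                       generate_replicates, generate_siblings)
from .variance import (add_variance_components, descriptive_variances,
                       detect_outlier_subsets, mean_normalize,
                       regress_within_on_between)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and resampling sizes for a full pipeline run."""

    out_dir: str | Path = "cytomevar_out"
    # either file inputs ...
    observations: str | Path | None = None
    replicates: str | Path | None = None
    siblings: str | Path | None = None
    catalog: str | Path | None = None
    # ... or a generator configuration
    generator: GeneratorConfig | None = None
    seed: int = 0
    strict: bool = True
    n_permutations: int = 999
    n_resamples: int = 999
    q_threshold: float = 0.05
    rho_threshold: float = 0.0
    outlier_field: str = "var_technical"
    outlier_fence_k: float = 3.0
    reference_visit: int = 1
    run_permutation: bool = True
    run_fluctuation: bool = True
    run_siblings: bool = True
    run_multivariate: bool = True
    group_field: str = "sex"

    def __post_init__(self):
        if self.run_multivariate:
            self.run_fluctuation = True  # PCA/correlations need the summary
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in [0, 1]")
        if self.rho_threshold < 0 or self.outlier_fence_k <= 0:
            raise ValueError("thresholds out of range")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)

    def config_hash(self) -> str:
        as_dict = dataclasses.asdict(self)
        as_dict.pop("out_dir")           # where outputs land is not analytic
        for key in ("observations", "replicates", "siblings", "catalog"):
            if as_dict[key] is not None:
                as_dict[key] = str(as_dict[key])
        blob = json.dumps(as_dict, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _load_inputs(config: RunConfig):
    if config.generator is not None:
        gen = config.generator
        catalog = catalog_frame(gen)
        obs, manifest = generate_cohort(gen)
        reps = generate_replicates(gen)
        sibs, sib_manifest = generate_siblings(gen)
        return obs, reps, sibs, catalog, {"cohort": manifest,
                                          "siblings": sib_manifest}
    if config.observations is None:
        raise ValueError("RunConfig needs either observation paths or a generator")
    catalog = io.read_catalog(config.catalog) if config.catalog else None
    obs = io.read_observations(config.observations, catalog, config.strict)
    reps = (io.read_replicates(config.replicates, catalog, config.strict)
            if config.replicates else None)
    sibs = (io.read_siblings(config.siblings, catalog, config.strict)
            if config.siblings else None)
    return obs, reps, sibs, catalog, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash()}
    stage = "load"
    try:
        obs, reps, sibs, catalog, manifests = _load_inputs(config)
        if manifests is not None:        # synthetic run: persist the inputs
            io.write_table(obs, out / "observations.csv")
            io.write_table(reps, out / "replicates.csv")
            io.write_table(sibs, out / "siblings.csv")
            io.write_table(catalog, out / "catalog.csv")
            _write_json(out / "truth_manifest.json", manifests)

        stage = "normalize"
        norm = mean_normalize(obs)
        norm_reps = mean_normalize(reps) if reps is not None else None

        stage = "descriptive_variances"
        var_summary = descriptive_variances(norm, norm_reps)

        stage = "outlier_exclusion"
        if var_summary[config.outlier_field].notna().any():
            flags = detect_outlier_subsets(var_summary, config.outlier_field,
                                           config.outlier_fence_k)
            excluded = flags.loc[flags["flagged"], "subset_id"].tolist()
        else:
            flags = None
            excluded = []
        retained = [s for s in var_summary["subset_id"] if s not in excluded]
        _write_json(out / "exclusions.json", {
            "field": config.outlier_field, "fence_k": config.outlier_fence_k,
            "excluded": excluded, "retained": retained})
        norm_kept = norm[norm["subset_id"].isin(retained)]
        obs_kept = obs[obs["subset_id"].isin(retained)]
        kept_summary = var_summary[var_summary["subset_id"].isin(retained)]

        stage = "variance_components"
        kept_summary = add_variance_components(kept_summary, norm_kept)
        var_summary = (var_summary.set_index("subset_id")
                       .combine_first(kept_summary.set_index("subset_id"))
                       .loc[var_summary["subset_id"]].reset_index())
        io.write_table(var_summary[kept_summary.columns], out / "variance_summary.csv")

        stage = "variance_regression"
        reg = {"unadjusted": regress_within_on_between(kept_summary, False)}
        if kept_summary["var_technical"].notna().sum() >= 5:
            reg["technical_adjusted"] = regress_within_on_between(kept_summary, True)
        _write_json(out / "regression.json", reg)

        perm = rc = None
        if config.run_permutation:
            stage = "permutation_tests"
            perm = permutation_test_all(norm_kept, config.n_permutations,
                                        config.seed)
            io.write_table(perm, out / "permtest_results.csv")

        if config.run_fluctuation:
            stage = "fluctuation"
            z = zscore_transform(obs_kept)
            fluct = individual_baseline_fluctuation(z)
            io.write_table(fluct, out / "fluctuation_summary.csv")
            mv = mean_variance_correlation_all(fluct)
            io.write_table(mv, out / "meanvar_correlations.csv")
            rc = rank_concordance(kept_summary[["subset_id", "var_between"]], mv)
            _write_json(out / "rank_concordance.json", dataclasses.asdict(rc))

        if config.run_multivariate:
            stage = "multivariate"
            scree_rows, score_frames = [], []
            for what in ("baseline", "fluctuation", "both"):
                X = feature_matrix(fluct, what).dropna(axis=0, how="any")
                pca = pca_individuals(X, standardize=True)
                scree_rows.extend(
                    (what, k + 1, r) for k, r in
                    enumerate(pca.explained_variance_ratio))
                sc = pca.scores.iloc[:, :2].copy()
                sc.insert(0, "features", what)
                score_frames.append(sc.reset_index(names="individual_id"))
            io.write_table(pd.concat(score_frames, ignore_index=True),
                           out / "pca_scores.csv")
            io.write_table(pd.DataFrame(
                scree_rows, columns=["features", "component",
                                     "explained_variance_ratio"]),
                out / "pca_scree.csv")

            Xb = feature_matrix(fluct, "baseline").dropna(axis=0, how="any")
            cm = correlation_matrix(Xb)
            io.write_table(cm.long_form(), out / "correlation_matrix.csv")
            edges = correlation_network(cm, config.q_threshold,
                                        config.rho_threshold, catalog)
            io.write_table(edges, out / "network_edges.csv")
            summary["n_network_edges"] = int(len(edges))

            stage = "group_comparison"
            gc = group_comparison(obs_kept, config.group_field)
            io.write_table(gc, out / "group_comparison.csv")
            summary["n_sex_significant_bonferroni"] = int(
                (gc["p_bonferroni"] < 0.05).sum())

        if config.run_siblings and sibs is not None:
            stage = "siblings"
            ref = reference_from_observations(obs_kept, config.reference_visit)
            n_pairs_max = (sibs.groupby("family_id")["individual_id"].nunique()
                           .apply(lambda k: k * (k - 1) // 2).sum())
            allow = 2 * n_pairs_max > ref["individual_id"].nunique()
            if allow:
                logger.warning("reference cohort too small for disjoint null "
                               "pairs; sampling pairs with overlap")
            sib_res = sibling_concordance_all(
                sibs[sibs["subset_id"].isin(retained)], ref,
                config.n_resamples, config.seed, allow_overlap=allow)
            io.write_table(sib_res, out / "sibling_results.csv")
            summary["n_sibling_concordant_q05"] = int(
                (sib_res["q_value"] < 0.05).sum())

        summary.update({
            "n_individuals": int(obs["individual_id"].nunique()),
            "n_subsets_total": int(var_summary["subset_id"].nunique()),
            "excluded_subsets": excluded,
            "prop_within_median": float(kept_summary["prop_within"].median()),
            "regression_adj_r2": reg["unadjusted"].adjusted_r_squared,
            "regression_t": reg["unadjusted"].t_value,
        })
        if perm is not None:
            summary["n_between_gt_within_q05"] = int(
                (perm["q_value"] < 0.05).sum())
        if rc is not None:
            summary["rank_concordance_rho"] = rc.spearman_rho
            summary["rank_concordance_p"] = rc.p_value
        _write_json(out / "summary.json", summary)
        _write_json(out / "run_info.json", {
            "version": __version__, "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config)})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return summary
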