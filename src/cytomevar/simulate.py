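"""Hierarchical synthetic cohorts of immune-subset frequencies.

The generative model mirrors the structure a serially-bled immunophenotyping
study assumes.  For individual *i* and subset *s* with population mean
``mu_s`` (% of parent gate):

* a stable per-individual baseline on the log scale,
  ``b_is ~ Normal(0, sigma_b^2)`` — baselines are lognormal across
  individuals, i.e. positive and right-skewed;
* visit-level fluctuation ``e_ijs ~ Normal(0, (sigma_w * exp(kappa * b_is))^2)``
  expressed relative to the subset's population scale — with ``kappa > 0``
  individuals sitting high also fluctuate more ("environmentally
  responsive" subsets), with ``kappa = 0`` the visit-to-visit spread is the
  same for everyone (a stable subset);
* the observed frequency
  ``y_ijs = clamp(mu_s * (exp(b_is) + e_ijs), 0, 100)``.

The fluctuation enters additively at the subset scale rather than inside
the exponential on purpose: multiplicative visit noise would make every
individual's fluctuation proportional to their baseline, so *every* subset
would carry a baseline-fluctuation coupling and ``kappa`` could not single
out the responsive ones.  Clamping (at 0 for rare subsets with large
fluctuation, at 100 for abundant ones) is logged and rare under the default
configuration.

Technical replicates perturb a fixed latent control value per subset by
lognormal noise whose coefficient of variation is ``technical_cv`` (times an
optional per-subset multiplier, modelling subsets that are technically hard
to gate).  Sibling cohorts share a fraction ``sibling_shared_fraction`` of
the between-individual baseline variance within each family.

Each table draws from its own random stream derived from the master seed by
a fixed offset, so e.g. generating replicates never perturbs cohort values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# fixed stream offsets per table
_STREAM_COHORT = 11
_STREAM_REPLICATES = 13
_STREAM_SIBLINGS = 17
_STREAM_DEMOGRAPHICS = 19


@dataclass
class SubsetSpec:
    """Generative parameters of one immune subset.

    Parameters
    ----------
    mu : population scale of the frequency, % of parent gate, in (0, 100).
    sigma_b : between-individual SD of the log-scale baseline.
    sigma_w : within-individual (visit-level) SD, as a fraction of ``mu``.
    kappa : mean-variance coupling; 0 = stable subset, >0 = responsive.
    technical_cv_multiplier : scales the run-level technical CV for this
        subset (models gating-difficulty differences, e.g. very rare subsets).
    """

    subset_id: str
    mu: float
    sigma_b: float
    sigma_w: float
    kappa: float = 0.0
    technical_cv_multiplier: float = 1.0
    label: str = ""
    parent_gate_id: str = "live PBMC"
    marker_text: str = ""

    def __post_init__(self):
        if not 0.0 < self.mu < 100.0:
            raise ValueError(f"{self.subset_id}: mu must be in (0, 100), got {self.mu}")
        if self.sigma_b < 0 or self.sigma_w < 0:
            raise ValueError(f"{self.subset_id}: sigma_b/sigma_w must be >= 0")
        if self.kappa < 0:
            raise ValueError(f"{self.subset_id}: kappa must be >= 0")
        if not self.label:
            self.label = self.subset_id


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic study."""

    n_individuals: int = 43
    n_visits: int = 4
    subsets: list[SubsetSpec] = field(default_factory=lambda: default_subsets())
    technical_cv: float = 0.04
    n_replicate_runs: int = 40
    n_families: int = 37
    siblings_per_family: int = 2
    sibling_shared_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_individuals", "n_visits", "n_replicate_runs",
                     "n_families", "siblings_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.sibling_shared_fraction <= 1.0:
            raise ValueError("sibling_shared_fraction must be in [0, 1]")
        if self.technical_cv < 0:
            raise ValueError("technical_cv must be >= 0")
        self.subsets = [s if isinstance(s, SubsetSpec) else SubsetSpec(**s)
                        for s in self.subsets]
        ids = [s.subset_id for s in self.subsets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subset_id in subsets")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown generator config key(s): {sorted(unknown)}")
        return cls(**raw)


# Display names follow the gating scheme of a broad PBMC immunophenotyping
# panel (T/B/NK/monocyte/DC compartments plus regulatory and unconventional
# T cells).  Means span orders of magnitude, as real %-of-parent data do.
# Responsive subsets (plasmablasts, EMRA/TEMRA, gamma-delta T, inflammatory
# monocytes) couple fluctuation to baseline (kappa=1) and show within-
# individual variance comparable to between-individual variance; stable
# subsets (naive/memory lymphocytes, classical monocytes) fluctuate much
# less than they differ between individuals.  iNKT carries an 8x technical-CV
# multiplier: a very rare subset whose gating is technically noisy.
_RESPONSIVE = {"plasmablast", "plasmablast_iga", "cd4_emra", "cd8_emra",
               "gd_t", "mono_inflammatory"}

_SUBSET_TABLE = [
    # subset_id, label, parent, mu (% of parent), scale class
    ("b_cell", "B cell", "live PBMC", 10.0, "mid"),
    ("b_immature", "B immature", "b_cell", 6.0, "mid"),
    ("b_memory", "B memory", "b_cell", 25.0, "low"),
    ("b_naive", "B naive", "b_cell", 60.0, "low"),
    ("b1_cell", "B1 B cell", "b_cell", 2.5, "mid"),
    ("plasmablast", "Plasmablast", "b_cell", 1.2, "high"),
    ("plasmablast_iga", "Plasmablast IgA+", "plasmablast", 20.0, "high"),
    ("plasmablast_igg", "Plasmablast IgG+", "plasmablast", 30.0, "mid"),
    ("treg", "Treg", "cd4_t", 6.0, "low"),
    ("treg_cd39_i", "CD39+ iTreg", "itreg", 30.0, "mid"),
    ("treg_cd39_n", "CD39+ nTreg", "ntreg", 40.0, "mid"),
    ("treg_cd39", "CD39+ Treg", "treg", 35.0, "mid"),
    ("itreg", "iTreg", "treg", 45.0, "mid"),
    ("ntreg", "nTreg", "treg", 50.0, "low"),
    ("cd4_t", "CD4", "t_cell", 55.0, "low"),
    ("cd4_naive", "CD4 naive", "cd4_t", 45.0, "low"),
    ("cd4_memory", "CD4 memory", "cd4_t", 35.0, "low"),
    ("cd4_emra", "CD4 EMRA", "cd4_t", 3.0, "high"),
    ("cd8_t", "CD8", "t_cell", 25.0, "low"),
    ("cd8_naive", "CD8 naive", "cd8_t", 40.0, "low"),
    ("cd8_memory", "CD8 memory", "cd8_t", 30.0, "low"),
    ("cd8_emra", "CD8 EMRA", "cd8_t", 15.0, "high"),
    ("dc", "Dendritic cell", "live PBMC", 1.5, "mid"),
    ("mdc", "mDC", "dc", 60.0, "mid"),
    ("pdc", "pDC", "dc", 30.0, "mid"),
    ("monocyte", "Monocyte", "live PBMC", 15.0, "mid"),
    ("mono_classical", "Monocyte Classical", "monocyte", 80.0, "low"),
    ("mono_inflammatory", "Monocyte Inflammatory", "monocyte", 6.0, "high"),
    ("mono_patrolling", "Monocyte Patrolling", "monocyte", 5.0, "mid"),
    ("nk_cell", "NK cell", "live PBMC", 8.0, "mid"),
    ("nk_cd56bright", "NK CD56bright", "nk_cell", 6.0, "mid"),
    ("t_cell", "T cell", "live PBMC", 60.0, "low"),
    ("gd_t", "Gamma delta T cell", "t_cell", 4.0, "high"),
    ("nkt", "NKT", "t_cell", 5.0, "mid"),
    ("inkt", "iNKT", "t_cell", 0.08, "mid"),
]

# log-scale between-individual SD per class, and the within/between SD ratio.
_SCALE_CLASS = {"low": 0.15, "mid": 0.30, "high": 0.50}
_RATIO_CYCLE = {"low": (0.40, 0.55, 0.70), "mid": (0.45, 0.60, 0.70),
                "high": (0.95,)}


def default_subsets() -> list[SubsetSpec]:
    """The default 35-subset catalog at the study's scale."""
    specs = []
    counters: dict[str, int] = {}
    for subset_id, label, parent, mu, cls in _SUBSET_TABLE:
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        sigma_b = _SCALE_CLASS[cls]
        ratio = _RATIO_CYCLE[cls][k % len(_RATIO_CYCLE[cls])]
        specs.append(SubsetSpec(
            subset_id=subset_id, label=label, parent_gate_id=parent,
            mu=mu, sigma_b=sigma_b, sigma_w=ratio * sigma_b,
            kappa=1.0 if subset_id in _RESPONSIVE else 0.0,
            technical_cv_multiplier=8.0 if subset_id == "inkt" else 1.0,
            marker_text=""))
    return specs


def catalog_frame(config: GeneratorConfig) -> pd.DataFrame:
    """The subset catalog implied by a generator configuration."""
    return pd.DataFrame(
        [(s.subset_id, s.label, s.parent_gate_id, s.marker_text)
         for s in config.subsets],
        columns=["subset_id", "label", "parent_gate_id", "marker_text"])


def _rng(config: GeneratorConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, config.seed])


def _individual_ids(n: int, prefix: str = "I") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _demographics(config: GeneratorConfig, ids: list[str]):
    """Sex and age per individual (young-adult cohort, ~25.8 +/- 1.8 y)."""
    rng = _rng(config, _STREAM_DEMOGRAPHICS)
    sex = np.where(rng.random(len(ids)) < 25 / 43, "M", "F")
    age = np.round(np.clip(rng.normal(25.8, 1.8, len(ids)), 18.0, None), 1)
    return dict(zip(ids, sex)), dict(zip(ids, age))


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the longitudinal cohort.

    Returns the observation table (complete individuals x visits x subsets
    grid) and a truth manifest holding every latent baseline ``b_is`` and all
    subset parameters.  Deterministic given ``config.seed``.
    """
    rng = _rng(config, _STREAM_COHORT)
    ids = _individual_ids(config.n_individuals)
    sex_of, age_of = _demographics(config, ids)
    n_i, n_j = config.n_individuals, config.n_visits

    base_date = np.datetime64("2014-01-06")
    frames = []
    baselines: dict[str, dict[str, float]] = {}
    n_clamped = 0
    for spec in config.subsets:
        b = rng.normal(0.0, spec.sigma_b, size=n_i)
        sd_w = spec.sigma_w * np.exp(spec.kappa * b)
        e = rng.normal(0.0, 1.0, size=(n_i, n_j)) * sd_w[:, None]
        raw = spec.mu * (np.exp(b)[:, None] + e)
        n_clamped += int(np.count_nonzero((raw > 100.0) | (raw < 0.0)))
        y = np.clip(raw, 0.0, 100.0)
        baselines[spec.subset_id] = {ind: float(v) for ind, v in zip(ids, b)}
        frames.append(pd.DataFrame({
            "individual_id": np.repeat(ids, n_j),
            "visit_index": np.tile(np.arange(1, n_j + 1), n_i),
            "subset_id": spec.subset_id,
            "frequency_pct": y.ravel(),
        }))
    obs = pd.concat(frames, ignore_index=True)
    # quarterly draws, start staggered by recruitment order
    offsets = {ind: 7 * k for k, ind in enumerate(ids)}
    obs["collection_date"] = [
        str(base_date + offsets[i] + 91 * (v - 1))
        for i, v in zip(obs["individual_id"], obs["visit_index"])
    ]
    obs["sex"] = obs["individual_id"].map(sex_of)
    obs["age_years"] = obs["individual_id"].map(age_of)
    obs = obs[["individual_id", "visit_index", "collection_date", "sex",
               "age_years", "subset_id", "frequency_pct"]]
    if n_clamped:
        logger.warning("generate_cohort: clamped %d value(s) at 100%%", n_clamped)
    manifest = {
        "seed": config.seed,
        "kind": "cohort",
        "n_clamped": n_clamped,
        "subsets": [asdict(s) for s in config.subsets],
        "baseline": baselines,
    }
    return obs, manifest


def generate_replicates(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the control sample stained once per acquisition run.

    One fixed latent value per subset (its population mean) perturbed per run
    by lognormal noise whose CV equals ``technical_cv *
    technical_cv_multiplier`` for that subset.
    """
    rng = _rng(config, _STREAM_REPLICATES)
    runs = [f"R{r + 1:03d}" for r in range(config.n_replicate_runs)]
    frames = []
    for spec in config.subsets:
        cv = config.technical_cv * spec.technical_cv_multiplier
        sigma_ln = np.sqrt(np.log1p(cv * cv))  # lognormal CV identity
        y = np.clip(spec.mu * np.exp(rng.normal(0.0, sigma_ln, len(runs))),
                    0.0, 100.0)
        frames.append(pd.DataFrame(
            {"run_id": runs, "subset_id": spec.subset_id, "frequency_pct": y}))
    return pd.concat(frames, ignore_index=True)


def generate_siblings(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the family cohort: one observation per sibling per subset.

    Per family and subset a shared baseline component
    ``g ~ Normal(0, f * sigma_b^2)`` is drawn (``f`` =
    ``sibling_shared_fraction``); each sibling adds an independent
    ``u ~ Normal(0, (1 - f) * sigma_b^2)`` and a visit-level fluctuation with
    the same mean-variance coupling as the longitudinal cohort.
    """
    rng = _rng(config, _STREAM_SIBLINGS)
    n_f, n_s = config.n_families, config.siblings_per_family
    fam_ids = [f"F{f + 1:02d}" for f in range(n_f)]
    ids = [f"{fam}S{s + 1}" for fam in fam_ids for s in range(n_s)]
    sex_of, age_of = _demographics(config, ids)
    share = config.sibling_shared_fraction

    frames = []
    shared: dict[str, dict[str, float]] = {}
    baselines: dict[str, dict[str, float]] = {}
    for spec in config.subsets:
        g = rng.normal(0.0, np.sqrt(share) * spec.sigma_b, size=n_f)
        u = rng.normal(0.0, np.sqrt(1.0 - share) * spec.sigma_b, size=(n_f, n_s))
        b = g[:, None] + u
        sd_w = spec.sigma_w * np.exp(spec.kappa * b)
        e = rng.normal(0.0, 1.0, size=(n_f, n_s)) * sd_w
        y = np.clip(spec.mu * (np.exp(b) + e), 0.0, 100.0)
        shared[spec.subset_id] = {fam: float(v) for fam, v in zip(fam_ids, g)}
        baselines[spec.subset_id] = {ind: float(v)
                                     for ind, v in zip(ids, b.ravel())}
        frames.append(pd.DataFrame({
            "family_id": np.repeat(fam_ids, n_s),
            "individual_id": ids,
            "subset_id": spec.subset_id,
            "frequency_pct": y.ravel(),
        }))
    sib = pd.concat(frames, ignore_index=True)
    sib["sex"] = sib["individual_id"].map(sex_of)
    sib["age_years"] = sib["individual_id"].map(age_of)
    sib = sib[["family_id", "individual_id", "sex", "age_years",
               "subset_id", "frequency_pct"]]
    manifest = {
        "seed": config.seed,
        "kind": "siblings",
        "sibling_shared_fraction": share,
        "subsets": [asdict(s) for s in config.subsets],
        "family_shared": shared,
        "baseline": baselines,
    }
    return sib, manifest
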