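import numpy as np
import pandas as pd
import pytest

import cytomevar as cv


@pytest.fixture
def tiny_obs() -> pd.DataFrame:
    """Two individuals x two visits x one subset, hand-enterable numbers."""
    rows = []
    for ind, vals in [("A", [1.0, 3.0]), ("B", [5.0, 7.0])]:
        for visit, val in enumerate(vals, start=1):
            rows.append((ind, visit, "", "M", 25.0, "s1", val))
    return pd.DataFrame(rows, columns=cv.io.OBS_COLUMNS)


@pytest.fixture
def small_config() -> cv.GeneratorConfig:
    """A small but structurally complete synthetic study."""
    subsets = [
        cv.SubsetSpec("alpha", 40.0, 0.20, 0.10, 0.0),
        cv.SubsetSpec("beta", 5.0, 0.40, 0.20, 0.0),
        cv.SubsetSpec("gamma", 1.0, 0.50, 0.45, 1.0),
        cv.SubsetSpec("delta", 0.2, 0.30, 0.20, 0.0),
        cv.SubsetSpec("epsilon", 12.0, 0.25, 0.12, 0.0),
    ]
    return cv.GeneratorConfig(n_individuals=12, n_visits=4, subsets=subsets,
                              technical_cv=0.05, n_replicate_runs=12,
                              n_families=8, sibling_shared_fraction=0.5,
                              seed=20240101)


@pytest.fixture
def small_cohort(small_config):
    obs, manifest = cv.generate_cohort(small_config)
    return obs, manifest


def make_obs(values_by_individual: dict[str, list[float]],
             subset_id: str = "s1") -> pd.DataFrame:
    """Build an observation table from per-individual visit values."""
    rows = []
    for ind, vals in values_by_individual.items():
        for visit, val in enumerate(vals, start=1):
            rows.append((ind, visit, "", "unknown", 30.0, subset_id, float(val)))
    return pd.DataFrame(rows, columns=cv.io.OBS_COLUMNS)
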