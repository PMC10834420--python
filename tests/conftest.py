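import numpy as np
import pandas as pd
import pytest

from clonmosaic.synthetic import CohortConfig, simulate_cohort


def small_trio_config(seed=2, n_cases=4, **overrides):
    """Trio cohort at reduced burden for fast unit tests (study-scale
    burdens are exercised in the acceptance suite)."""
    base = dict(
        n_cases=n_cases,
        seed=seed,
        burden_slope_by_tissue={"normal": 2.0, "BPH": 2.0, "PCA": 2.0},
        burden_intercept_by_tissue={"normal": 30.0, "BPH": 30.0, "PCA": 60.0},
        n_germline=10,
        n_artifact_sites=5,
    )
    base.update(overrides)
    return CohortConfig(**base)


def small_grid_config(seed=0, pattern="layered", **overrides):
    base = dict(
        n_cases=1,
        design="grid3d",
        grid_dims=(4, 4, 4),
        eem_pattern=pattern,
        seed=seed,
        burden_slope_by_tissue={"normal": 0.5, "BPH": 0.5, "PCA": 0.5},
        burden_intercept_by_tissue={"normal": 5.0, "BPH": 5.0, "PCA": 5.0},
        n_germline=5,
        n_artifact_sites=3,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def trio_cohort():
    """One small trio cohort shared across tests (read-only)."""
    return simulate_cohort(small_trio_config())


@pytest.fixture(scope="session")
def grid_cohort():
    return simulate_cohort(small_grid_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
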