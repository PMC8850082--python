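import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import oxbalance as ox

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return ox.load_default_schema()


@pytest.fixture(scope="session")
def cutpoints():
    return ox.load_default_cutpoints()


def make_clean_cohort(n=400, seed=11, **overrides):
    """Small synthetic cohort with no planted violations."""
    cfg = ox.SimulationConfig(n=n, n_strata=overrides.pop("n_strata", 4),
                              seed=seed, **overrides)
    cohort, truth = ox.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    cohort, _ = make_clean_cohort()
    return cohort


@pytest.fixture(scope="session")
def small_cohort_truth():
    return make_clean_cohort()
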