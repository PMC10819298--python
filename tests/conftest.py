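import numpy as np
import pytest

from emergepd.cohort import CohortConfig, generate_cohort
from emergepd.greco import GrecoResponseSurface


@pytest.fixture(scope="session")
def surface():
    """The shipped volunteer-study interaction surface (OAA/S < 4 endpoint)."""
    return GrecoResponseSurface.from_preset("oaas_lt4").fit()


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size virtual cohort under the default study conditions."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def labeled_default(default_cohort):
    return default_cohort.labeled_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced cohort for plumbing tests (not the study conditions)."""
    return CohortConfig(
        n_patients=3,
        seed=11,
        op_time_mean_sd=(60.0, 5.0),
        dt_min=0.5,
        emergence_horizon_min=60.0,
    )
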