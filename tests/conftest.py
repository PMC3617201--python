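import numpy as np
import pytest

from oacrab.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def rkc_experiment():
    """One seeded red-king-crab experiment shared across tests."""
    return simulate_cohort(CohortConfig.red_king_crab(seed=20))


@pytest.fixture(scope="session")
def tanner_experiment():
    return simulate_cohort(CohortConfig.tanner(seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
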