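import numpy as np
import pytest
from hypothesis import settings

import reachadapt as ra

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_configs():
    return ra.default_study_configs(seed=7, n_per_group=4)


@pytest.fixture(scope="session")
def small_cohort(default_configs):
    """Trial-level four-group cohort, 4 participants per group."""
    return ra.simulate_cohort(default_configs, trajectories=False, seed=7)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free cohort: every pipeline estimate should equal its injection."""
    cfgs = [c.zero_noise() for c in ra.default_study_configs(seed=11, n_per_group=2)]
    return ra.simulate_cohort(cfgs, trajectories=False, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
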