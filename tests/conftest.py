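import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sedrate.rates import RateCalibration
from sedrate.synthetic import (SimulationConfig, default_community,
                               default_rate_calibration)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def community():
    return default_community()


@pytest.fixture
def rate_cal():
    return default_rate_calibration()


@pytest.fixture
def identity_cal():
    """R = F: handy when the fluorescence value *is* the expected rate."""
    return RateCalibration(a=1.0, b=1.0, f_min=1e-6, f_max=1e9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
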