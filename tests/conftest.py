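import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import barrelsim as bs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tc_weight():
    """Calibrated thalamocortical weight at full scale, shared across tests."""
    return bs.calibrate_tc_weight(6.0, seed=0)


@pytest.fixture(scope="session")
def chain_model(tc_weight):
    """Full five-column chain realisation, shared by structure and protocol tests."""
    return bs.build_chain(n_columns=5, w_tc=tc_weight, seed=0)


@pytest.fixture
def small_barrel(tc_weight):
    """A reduced barrel for fast engine-level checks."""
    return bs.build_barrel(w_tc=tc_weight, seed=2, scale=0.1)
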