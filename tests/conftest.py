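import numpy as np
import pytest

from mesovar.experiments import simulate_orientation_session, simulate_pulse_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pulse_tensor():
    """Small driven-network session reused by read-only analysis tests."""
    return simulate_pulse_session(7, amplitude=2.0, n_neurons=150, n_trials=8)


@pytest.fixture(scope="session")
def orientation_tensor():
    """Small 8-orientation session reused by decoding tests."""
    return simulate_orientation_session(11, n_neurons=200, n_per_class=4)
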