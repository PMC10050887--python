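import numpy as np
import pytest

from glunplast import Model, resting_state, calibrate_spike_command


@pytest.fixture(scope="session")
def model() -> Model:
    """Default model; building it once warms the jit and the rest/command
    caches shared by all protocol tests."""
    m = Model()
    resting_state(m.neuron, m.dt)
    calibrate_spike_command(m.neuron, m.dt)
    return m


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
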