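import numpy as np
import pytest

from cortexlimb.synthetic_data import SimulationConfig, generate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_session():
    """One desk-scale synthetic session shared across tests (read-only)."""
    config = SimulationConfig.test_scale()
    session, truth = generate_session(config, seed=11)
    return config, session, truth
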