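import numpy as np
import pytest

import sizevolve as sv


@pytest.fixture(scope="session")
def seed_net():
    return sv.seed_network()


@pytest.fixture(scope="session")
def mfl_net():
    return sv.mixed_feedback_network()


@pytest.fixture(scope="session")
def default_config():
    return sv.CycleConfig()


@pytest.fixture(scope="session")
def long_config():
    # ~430 cycles: enough for steady-state statistics
    return sv.CycleConfig(T_total=600.0)


@pytest.fixture(scope="session")
def mfl_record(mfl_net, long_config):
    """One long homeostatic lineage of the calibrated mixed-feedback model."""
    return sv.simulate_lineage(mfl_net, long_config, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
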