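import numpy as np
import pytest

from lrbcsim import LrbcConstants, TransportConfig, canonical_skin_model, run_transport


@pytest.fixture(scope="session")
def constants():
    return LrbcConstants()


@pytest.fixture(scope="session")
def baseline_590_small():
    """One modest canonical-model run at 590 nm, shared across tests."""
    model = canonical_skin_model(1.0, 590)
    return run_transport(model, TransportConfig(n_packets=20_000, seed=7))


@pytest.fixture(scope="session")
def baseline_780_small():
    model = canonical_skin_model(1.0, 780)
    return run_transport(model, TransportConfig(n_packets=10_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
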