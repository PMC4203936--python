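import numpy as np
import pytest

from ribosig.datasets import load_reporter_utrs
from ribosig.energy import load_model
from ribosig.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def nn37():
    return load_model("nn37")


@pytest.fixture(scope="session")
def mini():
    return load_model("mini")


@pytest.fixture(scope="session")
def reporters():
    return load_reporter_utrs()


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated experiment shared across tests."""
    cfg = SimulationConfig(n_genes=40, library_size=20_000, seed=5)
    txome, counts = simulate_experiment(cfg)
    return cfg, txome, counts


@pytest.fixture
def rng():
    return np.random.default_rng(42)
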