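import numpy as np
import pytest

from contactzone import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_transect():
    """A small but complete simulated contact zone shared across tests."""
    cfg = sd.SimulationConfig(n_individuals=220, n_diagnostic_snps=30,
                              n_background_snps=60, f1_rate=0.01, seed=0)
    return sd.simulate_transect(cfg)
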