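import numpy as np
import pytest

from exitscreen import GateConfig, SimulationConfig, simulate_screen, standard_arms


@pytest.fixture(scope="session")
def arms():
    return standard_arms()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_screen():
    """One full plate (86 genes), all six arms, two replicates."""
    cfg = SimulationConfig(n_genes=86, events_per_well=2000, seed=11)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def gates():
    return GateConfig(min_gated_events=1000)
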