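import numpy as np
import pytest

from pgenmi.simulate import PopulationSimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A small simulated population shared by evidence/ranking/CLI tests."""
    cfg = PopulationSimConfig(
        n_individuals=120,
        n_genes=250,
        n_mediator_genes=12,
        n_decoy_tfs=2,
        seed=11,
    )
    data, truth = simulate_population(cfg)
    return cfg, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
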