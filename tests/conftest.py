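import numpy as np
import pytest

from editevol import simulate


@pytest.fixture(scope="session")
def small_truth():
    """A small neutral-regime dataset shared across tests."""
    cfg = simulate.SimConfig(n_sites=60, rng_seed=42)
    levels, truth = simulate.simulate_levels(cfg)
    return cfg, levels, truth


@pytest.fixture(scope="session")
def small_sequences(small_truth):
    cfg, levels, truth = small_truth
    seqs, site_table = simulate.simulate_sequences(truth, cfg)
    return cfg, truth, seqs, site_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
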