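import numpy as np
import pytest

from meaburst import GeneratorConfig, generate_dataset, standard_layout


@pytest.fixture(scope="session")
def layout():
    return standard_layout()


@pytest.fixture(scope="session")
def small_dataset():
    """Two superbursts of 40 small bursts each, default motif structure."""
    cfg = GeneratorConfig(seed=11, n_superbursts=2,
                          small_bursts_per_superburst=(40, 40),
                          inter_superburst_gap=(90.0, 120.0))
    spikes, truth = generate_dataset(cfg)
    return cfg, spikes, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
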