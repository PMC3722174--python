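import numpy as np
import pytest

from exondys.synthetic import GeneratorConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Default planted scenario at desk scale, shared across tests."""
    return simulate(GeneratorConfig(n_genes=40, seed=7))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Same scenario with zero noise: every planted effect is exact."""
    return simulate(GeneratorConfig(n_genes=20, noise_sigma=0.0, affinity_sigma=0.3, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
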