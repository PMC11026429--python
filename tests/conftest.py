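import numpy as np
import pytest

from ksphase.simulate import SimScenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced-size default scenario: same Ks structure, fewer/shorter genes."""
    return SimScenario(genes_per_chromosome=12, codons_per_gene=200, seed=20240)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)
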