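import numpy as np
import pytest

from multisnp import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A 60-locus, 60-individual panel shared by fast end-to-end tests."""
    cfg = SimConfig(seed=20240927, n_loci=60, population_size=60)
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
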