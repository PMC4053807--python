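import numpy as np
import pytest

from areclip.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial study: enough genes/sites for distributional
    checks without slowing the suite."""
    return SyntheticConfig(n_genes=300, n_sites=800, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study conditions (2000 genes, 3000 sites)."""
    return simulate(SyntheticConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
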