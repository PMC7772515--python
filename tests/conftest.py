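import numpy as np
import pytest

from spinelab import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ca1_config():
    """CA1 proximal stratum radiatum preset (the best-characterised region)."""
    return synthetic.REGION_PRESETS["CA1_PSR"].with_seed(7)


@pytest.fixture(scope="session")
def ca1_dataset(ca1_config):
    """A mid-sized CA1-like dataset shared across read-only tests."""
    return synthetic.generate_region(ca1_config, 30)
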