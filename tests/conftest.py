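import numpy as np
import pytest

from sonoscape import SynthConfig, generate_sites


@pytest.fixture(scope="session")
def small_config():
    """Tiny generator config shared by fast unit tests."""
    return SynthConfig(n_sites_per_class=2, n_days=1, seed=7, fast_frames=48)


@pytest.fixture(scope="session")
def small_sites(small_config):
    return generate_sites(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
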