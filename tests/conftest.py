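import numpy as np
import pytest

from kneeseg.phantom import PhantomConfig, generate_case, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom: 64x64 images, 24-slice stacks."""
    return PhantomConfig.default(n_cases=3, n_slices=24, image_size=64, seed=42)


@pytest.fixture(scope="session")
def noisefree_config():
    return PhantomConfig.default(n_cases=3, n_slices=24, image_size=64, noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def noisefree_cases(noisefree_config):
    return generate_dataset(noisefree_config)


@pytest.fixture(scope="session")
def one_case(small_config):
    return generate_case(small_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
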