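import numpy as np
import pytest

from mammogan.phantom import PhantomSpec, make_phantom, make_phantom_dataset, tiny_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sample():
    """One default-size (256x512) phantom with ground truth."""
    return make_phantom(PhantomSpec(seed=7), np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-domain phantom dataset with unpaired patch pools."""
    return make_phantom_dataset(8, tiny_spec(seed=5), seed=5)
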