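import numpy as np
import pytest

from tumorseg import GrayImage, PhantomSpec, generate_phantom


@pytest.fixture
def default_phantom():
    """One noisy phantom with tumor and brain truth masks."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def noiseless_phantom():
    """Noise-free phantom: exactly four intensity levels."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(arr, value_range=(0.0, 1.0)):
    return GrayImage(np.asarray(arr, dtype=float), value_range)
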