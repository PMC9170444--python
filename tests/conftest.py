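import numpy as np
import pytest

from fuzzyseg import GrayImage, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_membership(rng):
    """Factory for random f x n membership matrices with unit column sums."""

    def make(f=3, n=20):
        B = rng.random((f, n))
        return B / B.sum(axis=0)

    return make


@pytest.fixture
def two_blob_image(rng):
    """2-D image with two well-separated intensity groups around 0 and 100."""
    data = rng.normal(0.0, 0.5, (16, 16))
    data[8:, :] = rng.normal(100.0, 0.5, (8, 16))
    return GrayImage(data)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 32^3 four-tissue phantom (session-cached, read-only)."""
    return make_phantom((32, 32, 32), noise_level=0.0, seed=1)


@pytest.fixture(scope="session")
def phantom64():
    """Noiseless 64^3 phantom: tissue shells thicker than the 3x3x3
    smoothing window, the geometry the spatial term is designed for."""
    return make_phantom((64, 64, 64), noise_level=0.0, seed=1)
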