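import numpy as np
import pytest

from lascakit.imaging import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A small random non-negative intensity image."""
    return IntensityImage(rng.uniform(0, 200, size=(37, 41)))


def make_image(arr):
    return IntensityImage(np.asarray(arr, dtype=float))
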