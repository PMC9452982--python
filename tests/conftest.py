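import numpy as np
import pytest

from petfuse import Image2D, Modality


@pytest.fixture
def ramp_image():
    """8x8 linear ramp 0..63, row-major."""
    return Image2D(pixels=np.arange(64, dtype=float).reshape(8, 8))


@pytest.fixture
def halves_image():
    """16x16: left half 0, right half 255."""
    px = np.zeros((16, 16))
    px[:, 8:] = 255.0
    return Image2D(pixels=px, modality=Modality.CT)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
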