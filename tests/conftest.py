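import numpy as np
import pytest

from padenoise.image import Image2D, ROISpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gradient_image():
    """Smooth noise-free ramp, 64x64, values in [0, 1]."""
    r, c = np.mgrid[0:64, 0:64]
    return Image2D((r + c) / 126.0)


@pytest.fixture
def simple_roi():
    return ROISpec(signal_box=(0, 0, 8, 8), background_box=(8, 8, 16, 16))
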