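import numpy as np
import pytest

from mitofrac import BoxCountConfig, GrayscaleImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def origin_binary_cfg():
    """Single origin-anchored grid, binary counting, explicit dyadic scales."""
    return BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 2, 4, 8))


@pytest.fixture
def quadrant_image():
    """8x8 image with one filled 4x4 quadrant (known lacunarity at eps=4)."""
    px = np.zeros((8, 8))
    px[:4, :4] = 1.0
    return GrayscaleImage(px)
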