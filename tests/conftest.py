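import numpy as np
import pytest

from plumadrum.segmentation import MaskedImage
from plumadrum.synthetic_data import Patch, PlumageSpec, make_plumage_image


@pytest.fixture
def three_band_spec():
    """Black base with white and red bands: areas 0.5 / 0.3 / 0.2 exactly."""
    return PlumageSpec(
        width=100,
        height=100,
        base_color_lab=(12.0, 0.0, 0.0),
        patches=[
            Patch("band", (96.0, 0.0, 0.0), (0.5, 0.8)),
            Patch("band", (62.0, 60.0, 55.0), (0.8, 1.0)),
        ],
        noise_sd=0.0,
        mask_shape="full",
    )


@pytest.fixture
def three_band_image(three_band_spec):
    return make_plumage_image(three_band_spec)


@pytest.fixture
def uniform_image():
    pixels = np.full((10, 10, 3), [200, 30, 40], dtype=np.uint8)
    return MaskedImage(pixels=pixels, mask=np.ones((10, 10), bool))


def random_masked_image(rng, h=20, w=20):
    pixels = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    mask = rng.random((h, w)) < 0.8
    mask[0, 0] = True  # ensure at least one valid pixel
    return MaskedImage(pixels=pixels, mask=mask)
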