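import numpy as np
import pytest

from mitosig.synthetic.images import (
    DEFAULT_PIXEL_SIZE,
    SpectralImageSpec,
    synth_spectral_image,
)


@pytest.fixture(scope="session")
def pixel_size() -> float:
    return DEFAULT_PIXEL_SIZE


@pytest.fixture(scope="session")
def spectral_image_15(pixel_size):
    """One 512-px spectral-synthesis image with beta_true = 1.5."""
    return synth_spectral_image(
        SpectralImageSpec(beta_true=1.5, side_px=512, seed=7)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
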