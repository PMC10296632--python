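import numpy as np
import pytest

from msfnet import SynthConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """Ten small synthetic dermoscopy samples shared across tests."""
    return generate_synthetic(SynthConfig(n_images=10, image_size=(64, 80), seed=11))


def random_binary_mask(rng, shape, p=0.35):
    """A random blobby binary mask: thresholded smoothed noise."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2)
    mask = (noise > np.quantile(noise, 1 - p)).astype(np.uint8)
    return mask
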