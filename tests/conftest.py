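import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from okntrack.filterbank import build_filter_bank


def make_texture(shape=(192, 192), seed=7, sigma=1.5):
    """Smooth isotropic random texture with broad band-pass content."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), sigma)
    img -= img.min()
    img *= 255.0 / img.max()
    return img


def fft_shift(img, dx, dy=0.0):
    """Exact (spectral) sub-pixel translation; the shift-theorem oracle."""
    H, W = img.shape
    wy = 2 * np.pi * np.fft.fftfreq(H)[:, None]
    wx = 2 * np.pi * np.fft.fftfreq(W)[None, :]
    return np.fft.ifft2(np.fft.fft2(img) * np.exp(-1j * (wx * dx + wy * dy))).real


@pytest.fixture(scope="session")
def texture192():
    return make_texture((192, 192), seed=7)


@pytest.fixture(scope="session")
def bank192():
    return build_filter_bank((192, 192), 5, 4)


@pytest.fixture(scope="session")
def bank64():
    return build_filter_bank((64, 64), 3, 4)
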