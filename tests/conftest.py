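import numpy as np
import pytest

from nestcam import texture_features as tf


@pytest.fixture(scope="session")
def small_bank() -> tf.FilterBank:
    """Compact bank (2 scales x 3 orientations) for fast pipeline tests."""
    return tf.build_bank(scales=(3.0, 5.0), n_orientations=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def direct_convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force direct-summation spatial convolution with reflect padding.

    Independent oracle for the FFT-based implementation; O(HWk^2), only for
    tiny inputs.
    """
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    h, w = image.shape
    k = kernel.shape[0]
    out = np.zeros((h, w))
    flipped = kernel[::-1, ::-1]
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i:i + k, j:j + k] * flipped).sum()
    return out
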