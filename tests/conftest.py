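import numpy as np
import pytest

from rgscodec import phantom
from rgscodec.wavelet import IntCoeffPlane


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_image(seed: int, shape=(32, 32)) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 256, shape).astype(np.uint8)


def random_plane(seed: int, shape=(16, 16), levels=2, density=0.4, scale=60) -> tuple:
    """Sparse random integer coefficient plane plus its signed values."""
    r = np.random.default_rng(seed)
    vals = np.round(r.normal(0, scale, shape) * (r.random(shape) < density)).astype(np.int64)
    plane = IntCoeffPlane(
        magnitudes=np.abs(vals),
        signs=np.where(vals < 0, -1, 1).astype(np.int8),
        levels=levels,
        orig_shape=shape,
    )
    return plane, vals


@pytest.fixture
def clean_phantom():
    """Noise-free 256x256 phantom with ground truth."""
    return phantom.generate(phantom.PhantomSpec(seed=3, noise_sigma=0))
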