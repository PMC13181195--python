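"""Reading/writing 8-bit grayscale images and binary masks.

Images are plain ``uint8`` numpy arrays (H x W); masks are boolean arrays of
the same shape. Color inputs are collapsed to luma with the ITU-R BT.601
weights (0.299, 0.587, 0.114) and rounded.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .errors import DimMismatch

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a validated H x W uint8 image."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[:, :, :3]
        a = np.rint(a[:, :, :3].astype(np.float64) @ np.array(LUMA_WEIGHTS))
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any(a < 0) or np.any(a > 255):
            raise ValueError("intensities outside [0, 255]")
        a = a.astype(np.uint8)
    return a


def load_image(path) -> np.ndarray:
    """Read a PNG/PGM image as grayscale uint8."""
    return as_gray_image(iio.imread(path))


def save_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, as_gray_image(img))


def load_mask(path) -> np.ndarray:
    """Read a {0, 255} PNG mask as a boolean array."""
    return as_gray_image(iio.imread(path)) > 127


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def check_same_dims(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimMismatch(f"shape mismatch: {a.shape} vs {b.shape}")
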