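"""Biorthogonal 4.4 wavelet analysis/synthesis in Mallat layout.

The 2-D separable transform uses periodized filtering so every level halves
both dimensions exactly — the dyadic alignment the SPIHT spatial-orientation
tree requires. Images whose sides are not multiples of 2^(L+1) are padded
symmetrically before analysis and cropped after synthesis (the extra level of
divisibility keeps the coarsest LL even so its 2x2 root groups are complete).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ImageTooSmall
from .image_io import as_gray_image

WAVELET = "bior4.4"
_MODE = "periodization"
MAX_LEVELS = 6


@dataclass
class WaveletPyramid:
    """Mallat-layout coefficient plane (LL top-left, per-level LH/HL/HH)."""

    layout: np.ndarray  # padded_H x padded_W floats
    levels: int
    wavelet_id: str
    orig_shape: tuple[int, int]  # pre-padding image dims


@dataclass
class IntCoeffPlane:
    """Quantized coefficients split into magnitudes and signs."""

    magnitudes: np.ndarray  # non-negative int64
    signs: np.ndarray  # {+1, -1}; +1 wherever magnitude is 0
    levels: int
    orig_shape: tuple[int, int]


def decomposition_levels(n_row: int, n_col: int) -> int:
    """Number of levels: min(floor(log2(min dim)) - 2, 6), so coarsest LL >= 4x4."""
    if min(n_row, n_col) < 16:
        raise ImageTooSmall(f"need at least 16x16, got {n_row}x{n_col}")
    return min(int(np.floor(np.log2(min(n_row, n_col)))) - 2, MAX_LEVELS)


def _padded_shape(shape: tuple[int, int], levels: int) -> tuple[int, int]:
    step = 1 << (levels + 1)
    return tuple(-(-s // step) * step for s in shape)


def analyze(img: np.ndarray, levels: int | None = None) -> WaveletPyramid:
    """L-level bior4.4 decomposition into a single Mallat-arranged plane."""
    img = as_gray_image(img)
    h, w = img.shape
    if levels is None:
        levels = decomposition_levels(h, w)
    if levels < 1:
        raise ValueError("need at least one level")
    ph, pw = _padded_shape((h, w), levels)
    data = np.pad(img.astype(np.float64), ((0, ph - h), (0, pw - w)), mode="symmetric")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # pywt level heuristic
        coeffs = pywt.wavedec2(data, WAVELET, mode=_MODE, level=levels)
    arr, _ = pywt.coeffs_to_array(coeffs)
    return WaveletPyramid(layout=arr, levels=levels, wavelet_id=WAVELET, orig_shape=(h, w))


def _slices(shape: tuple[int, int], levels: int):
    """Coefficient slices for array_to_coeffs, recomputed from dims (dyadic halving)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        dummy = pywt.wavedec2(np.zeros(shape), WAVELET, mode=_MODE, level=levels)
    _, slices = pywt.coeffs_to_array(dummy)
    return slices


def synthesize(pyr: WaveletPyramid) -> np.ndarray:
    """Inverse transform to a real-valued plane cropped to the original dims.

    The caller clips to [0, 255] and rounds for display.
    """
    slices = _slices(pyr.layout.shape, pyr.levels)
    coeffs = pywt.array_to_coeffs(pyr.layout, slices, output_format="wavedec2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.waverec2(coeffs, WAVELET, mode=_MODE)
    h, w = pyr.orig_shape
    return rec[:h, :w]


def quantize(pyr: WaveletPyramid) -> IntCoeffPlane:
    """Round coefficients half-away-from-zero; split magnitude and sign."""
    a = pyr.layout
    q = np.sign(a) * np.floor(np.abs(a) + 0.5)
    mags = np.abs(q).astype(np.int64)
    signs = np.where((q < 0) & (mags > 0), -1, 1).astype(np.int8)
    return IntCoeffPlane(magnitudes=mags, signs=signs, levels=pyr.levels, orig_shape=pyr.orig_shape)


def dequantize(plane: IntCoeffPlane) -> WaveletPyramid:
    """Integer plane back to a (real) pyramid for synthesis."""
    layout = plane.magnitudes.astype(np.float64) * plane.signs
    return WaveletPyramid(
        layout=layout, levels=plane.levels, wavelet_id=WAVELET, orig_shape=plane.orig_shape
    )


def pyramid_from_plane(
    values: np.ndarray, levels: int, orig_shape: tuple[int, int]
) -> WaveletPyramid:
    """Wrap a real-valued Mallat plane (e.g. a SPIHT reconstruction)."""
    return WaveletPyramid(
        layout=np.asarray(values, dtype=np.float64),
        levels=levels,
        wavelet_id=WAVELET,
        orig_shape=orig_shape,
    )
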