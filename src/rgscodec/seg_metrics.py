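"""Segmentation evaluation: overlap ratios, confusion statistics, confidence intervals.

Conventions: two empty masks agree perfectly (Jaccard = Dice = 1); any 0/0 in
precision/recall/F is reported as 0. Confidence intervals use the printed
normal critical values z = 1.65 / 1.96 / 2.58 for 90 / 95 / 99 percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import ndimage

from .errors import DimMismatch, UnsupportedLevel
from .image_io import check_same_dims

Z_VALUES = {90: 1.65, 95: 1.96, 99: 2.58}


@dataclass
class SegScores:
    jaccard: float
    dice: float
    area_pct: float
    precision: float
    recall: float
    f_measure: float


@dataclass
class ConfidenceInterval:
    level: int
    z: float
    n: int
    lower: float
    upper: float


def _as_mask(m) -> np.ndarray:
    a = np.asarray(m)
    if a.ndim != 2:
        raise DimMismatch(f"mask must be 2-D, got shape {a.shape}")
    return a.astype(bool)


def jaccard(R, G) -> float:
    """|R ∩ G| / |R ∪ G|; 1 when both masks are empty."""
    R, G = _as_mask(R), _as_mask(G)
    check_same_dims(R, G)
    union = np.count_nonzero(R | G)
    if union == 0:
        return 1.0
    return np.count_nonzero(R & G) / union


def dice(R, G) -> float:
    """2|R ∩ G| / (|R| + |G|); 1 when both masks are empty."""
    R, G = _as_mask(R), _as_mask(G)
    check_same_dims(R, G)
    denom = np.count_nonzero(R) + np.count_nonzero(G)
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(R & G) / denom


def foreground_area_pct(mask) -> float:
    """Foreground pixels as a percentage of the frame."""
    m = _as_mask(mask)
    return 100.0 * np.count_nonzero(m) / m.size


def precision_recall_f(R, G, boundary: bool = False, band: int = 2) -> tuple[float, float, float]:
    """Pixel-wise precision/recall/F of mask R against ground truth G.

    With ``boundary=True`` the comparison is restricted to mask boundaries: a
    boundary pixel counts as a hit when the other mask's boundary passes
    within ``band`` pixels (Euclidean distance).
    """
    R, G = _as_mask(R), _as_mask(G)
    check_same_dims(R, G)
    if boundary:
        return _boundary_prf(R, G, band)
    tp = np.count_nonzero(R & G)
    fp = np.count_nonzero(R & ~G)
    fn = np.count_nonzero(~R & G)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))


def _boundary_prf(R: np.ndarray, G: np.ndarray, band: int) -> tuple[float, float, float]:
    br, bg = _boundary(R), _boundary(G)
    nr, ng = np.count_nonzero(br), np.count_nonzero(bg)
    if nr == 0 or ng == 0:
        return 0.0, 0.0, 0.0
    dist_to_g = ndimage.distance_transform_edt(~bg)
    dist_to_r = ndimage.distance_transform_edt(~br)
    precision = np.count_nonzero(br & (dist_to_g <= band)) / nr
    recall = np.count_nonzero(bg & (dist_to_r <= band)) / ng
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def score_masks(R, G) -> SegScores:
    """All scalar scores of predicted mask R against ground truth G."""
    p, r, f = precision_recall_f(R, G)
    return SegScores(
        jaccard=jaccard(R, G),
        dice=dice(R, G),
        area_pct=foreground_area_pct(R),
        precision=p,
        recall=r,
        f_measure=f,
    )


def confidence_interval(mean: float, sd: float, n: int, level: int = 95) -> ConfidenceInterval:
    """Normal-approximation CI: mean ∓ z·sd/√n with z from the printed table."""
    if level not in Z_VALUES:
        raise UnsupportedLevel(f"level must be one of {sorted(Z_VALUES)}, got {level}")
    if n < 2:
        raise ValueError("need at least two samples")
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    z = Z_VALUES[level]
    half = z * sd / sqrt(n)
    return ConfidenceInterval(level=level, z=z, n=n, lower=mean - half, upper=mean + half)
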