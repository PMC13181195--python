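"""ROI extraction by Otsu-seeded region growing combined with fuzzy c-means.

The informative region of a grayscale MR slice is found in four stages:

1. Otsu's method picks the intensity threshold maximizing between-class
   variance of the 256-bin histogram; pixels strictly above it form the
   provisional foreground.
2. The foreground pixel whose intensity is closest to the foreground mean
   becomes the seed of a breadth-first region growing that admits an
   8-connected frontier pixel whenever its intensity is within ``tol`` of the
   running region mean.
3. Fuzzy c-means (FCM) clusters every pixel on the 2-D feature
   ``(intensity, lambda * in_region)`` so the region-growing result enters
   the FCM objective as a spatial feature while the Euclidean distance of the
   classic objective is left intact.
4. The cluster overlapping the grown region most becomes the ROI; its hard
   (max-membership) mask is cleaned by hole filling and keeping the largest
   8-connected component.

All stages are deterministic given the configured RNG seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogram,
    EmptyForeground,
    InvalidFuzzifier,
    SeedOutOfBounds,
)
from .image_io import as_gray_image

# frontier enumeration order: N, S, W, E, NW, NE, SW, SE (fixed for determinism)
_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation pipeline.

    clusters        number of FCM clusters (2 = informative vs rest)
    fuzzifier       FCM weight exponent p > 1; p -> 1 approaches hard k-means
    lambda_spatial  scale of the region-growing indicator feature (intensity units)
    rg_tol_factor   region-growing tolerance as a fraction of the Otsu
                    between-class contrast |mean_fg - mean_bg|
    fcm_tol         convergence threshold on the max membership change
    max_iter        FCM iteration cap
    seed            RNG seed for centroid initialization
    """

    clusters: int = 2
    fuzzifier: float = 2.0
    lambda_spatial: float = 128.0
    rg_tol_factor: float = 0.15
    fcm_tol: float = 1e-5
    max_iter: int = 200
    seed: int = 0


@dataclass
class RegionGrowResult:
    mask: np.ndarray
    seed: tuple[int, int]
    region_mean: float
    tolerance: float


@dataclass
class FcmState:
    """Fuzzy c-means iterate: memberships U (n_points x m), centroids V (m x d)."""

    U: np.ndarray
    V: np.ndarray
    p: float
    m: int
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


@dataclass
class SegmentationResult:
    roi_mask: np.ndarray
    fcm: FcmState
    rg: RegionGrowResult
    otsu_threshold: int


def otsu_threshold(img: np.ndarray) -> int:
    """Threshold maximizing between-class variance; foreground is ``> t``.

    Ties in the variance scan are broken toward the smallest threshold.
    Raises DegenerateHistogram for a constant image.
    """
    img = as_gray_image(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("image has a single intensity value")
    n = hist.sum()
    p = hist / n
    levels = np.arange(256, dtype=np.float64)
    # class "background" = intensities <= t, "foreground" = > t
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu / w0
        mu1 = (mu_total - mu) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the smallest tie index


def select_seed(img: np.ndarray, t: int) -> tuple[int, int]:
    """Foreground pixel whose intensity is closest to the foreground mean.

    Ties are broken by the smallest row-major index. Raises EmptyForeground
    when nothing exceeds ``t``.
    """
    img = as_gray_image(img)
    fg = img > t
    if not fg.any():
        raise EmptyForeground(f"no pixel above threshold {t}")
    mean_fg = img[fg].mean()
    diff = np.where(fg, np.abs(img.astype(np.float64) - mean_fg), np.inf)
    idx = int(np.argmin(diff))  # row-major, smallest index on ties
    return (idx // img.shape[1], idx % img.shape[1])


def region_grow(img: np.ndarray, seed: tuple[int, int], tol: float) -> RegionGrowResult:
    """Breadth-first region growing around ``seed`` with 8-connectivity.

    A frontier pixel is admitted iff its intensity differs from the running
    region mean by at most ``tol``; the mean is updated after every
    admission. Each pixel is tested at most once (at its first visit), which
    makes the result deterministic and growth terminate.
    """
    img = as_gray_image(img)
    h, w = img.shape
    r0, c0 = seed
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise SeedOutOfBounds(f"seed {seed} outside {h}x{w} image")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")

    mask = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=bool)
    mask[r0, c0] = visited[r0, c0] = True
    total = float(img[r0, c0])
    count = 1
    queue = deque([(r0, c0)])
    pix = img  # local alias
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                visited[rr, cc] = True
                if abs(float(pix[rr, cc]) - total / count) <= tol:
                    mask[rr, cc] = True
                    total += float(pix[rr, cc])
                    count += 1
                    queue.append((rr, cc))
    return RegionGrowResult(mask=mask, seed=(r0, c0), region_mean=total / count, tolerance=float(tol))


def rg_fcm(
    img: np.ndarray,
    rg: RegionGrowResult,
    m: int = 2,
    p: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    rng_seed: int = 0,
    lambda_spatial: float = 128.0,
) -> FcmState:
    """Fuzzy c-means over per-pixel features ``(I_j, lambda * M_j)``.

    ``M_j`` is the region-growing membership indicator, so the spatial
    constraint enters the objective sum_{i,j} U_ij^p ||x_j - V_i||^2 as a
    feature dimension. Membership and centroid updates are the classical
    alternating-minimization formulas; centroids are initialized uniformly at
    random over the per-dimension data range from a seeded generator.
    """
    if m < 2:
        raise ValueError("need at least two clusters")
    if p <= 1:
        raise InvalidFuzzifier(f"fuzzifier must exceed 1, got {p}")
    if tol <= 0:
        raise ValueError("convergence tolerance must be positive")
    img = as_gray_image(img)
    X = np.column_stack(
        [img.ravel().astype(np.float64), lambda_spatial * rg.mask.ravel().astype(np.float64)]
    )  # n_points x 2
    n_points, d = X.shape
    rng = np.random.default_rng(rng_seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    V = lo + (hi - lo) * rng.random((m, d))

    exponent = 2.0 / (p - 1.0)
    U = _memberships(X, V, exponent)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Up = U**p
        denom = Up.sum(axis=0)
        # a cluster with zero total weight keeps its previous centroid
        live = denom > 0
        V_new = V.copy()
        V_new[live] = (Up.T @ X)[live] / denom[live, None]
        V = V_new
        trace.append(_objective(X, U, V, p))
        U_new = _memberships(X, V, exponent)
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            converged = True
            break
    return FcmState(U=U, V=V, p=p, m=m, objective_trace=trace, iterations=it, converged=converged)


def _sqdist(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, n_points x m."""
    return ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)


def _memberships(X: np.ndarray, V: np.ndarray, exponent: float) -> np.ndarray:
    d2 = _sqdist(X, V)
    zero = d2 <= 0.0
    U = np.empty_like(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exponent / 2.0)  # (1/d_ij)^(2/(p-1))
        U = inv / inv.sum(axis=1, keepdims=True)
    # coincident point/centroid: full membership to the first zero-distance cluster
    rows = np.nonzero(zero.any(axis=1))[0]
    for j in rows:
        U[j, :] = 0.0
        U[j, int(np.argmax(zero[j]))] = 1.0
    return U


def _objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, p: float) -> float:
    return float((U**p * _sqdist(X, V)).sum())


def extract_roi(fcm: FcmState, img: np.ndarray, rg: RegionGrowResult) -> np.ndarray:
    """Hard ROI mask from the FCM state.

    Pixels go to their maximum-membership cluster; the ROI cluster is the one
    overlapping the region-growing mask most (ties to the higher-intensity
    centroid); holes are filled and only the largest 8-connected component is
    kept.
    """
    img = as_gray_image(img)
    labels = np.argmax(fcm.U, axis=1).reshape(img.shape)
    rg_flat = rg.mask
    overlaps = np.array([np.count_nonzero((labels == i) & rg_flat) for i in range(fcm.m)])
    best = overlaps.max()
    tied = np.nonzero(overlaps == best)[0]
    if len(tied) > 1:  # tie: prefer the brighter centroid (intensity = feature 0)
        roi_cluster = int(tied[np.argmax(fcm.V[tied, 0])])
    else:
        roi_cluster = int(tied[0])
    mask = labels == roi_cluster
    if best == 0 and not rg_flat.any():
        # no spatial evidence at all: report an empty ROI
        return np.zeros_like(mask)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def segment(img: np.ndarray, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Full pipeline: Otsu -> seed -> region growing -> FCM -> ROI cleanup."""
    cfg = config or SegmentationConfig()
    img = as_gray_image(img)
    t = otsu_threshold(img)
    seed = select_seed(img, t)
    fg = img > t
    mean_fg = img[fg].mean()
    mean_bg = img[~fg].mean() if (~fg).any() else 0.0
    tol = cfg.rg_tol_factor * abs(mean_fg - mean_bg)
    rg = region_grow(img, seed, tol)
    fcm = rg_fcm(
        img,
        rg,
        m=cfg.clusters,
        p=cfg.fuzzifier,
        tol=cfg.fcm_tol,
        max_iter=cfg.max_iter,
        rng_seed=cfg.seed,
        lambda_spatial=cfg.lambda_spatial,
    )
    roi = extract_roi(fcm, img, rg)
    return SegmentationResult(roi_mask=roi, fcm=fcm, rg=rg, otsu_threshold=t)
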