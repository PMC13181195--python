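"""Seeded synthetic brain-like images with known ground-truth lesion masks.

Each phantom is an elliptical "head" of parenchyma over a dark background,
carrying one or more bright elliptical lesion blobs whose joint support is
the ground-truth ROI. A smooth multiplicative bias field and additive
Gaussian noise (optionally Rician, as MR magnitude noise really is) emulate
acquisition artifacts. Generation is bit-identical per seed.

The default contrast puts the lesion far above both tissue classes so the
histogram's Otsu foreground is the lesion itself — the bright-tumor contrast
the segmentation pipeline is designed around — and the default lesion area
is drawn from 2.5-8% of the frame, matching the foreground-area range of
typical tumor slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleSpec


@dataclass
class PhantomSpec:
    """Generation parameters; intensities are 8-bit levels."""

    seed: int = 0
    dims: tuple[int, int] = (256, 256)
    head_axes: tuple[float, float] = (0.82, 0.88)  # fractions of H/2, W/2
    tumor_count: int = 1
    tumor_area_pct: float | None = None  # None: drawn uniformly from [2.5, 8.0]
    tumor_intensity: int = 220
    tissue_intensity: int = 60
    background_intensity: int = 10
    bias_amplitude: float = 0.10  # multiplicative, +/- fraction
    noise_sigma: float = 0.0
    rician: bool = False


def _ellipse_mask(dims, center, semi_axes, angle) -> np.ndarray:
    h, w = dims
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bias_field(dims, amplitude, rng) -> np.ndarray:
    """Smooth low-frequency multiplicative field in [1-amp, 1+amp]."""
    h, w = dims
    y = np.linspace(0, 1, h)[:, None]
    x = np.linspace(0, 1, w)[None, :]
    ph = rng.uniform(0, 2 * np.pi, size=4)
    g = (
        np.sin(2 * np.pi * 0.7 * y + ph[0])
        + np.cos(2 * np.pi * 0.9 * x + ph[1])
        + np.sin(2 * np.pi * (0.5 * y + 0.6 * x) + ph[2])
        + np.cos(2 * np.pi * (0.8 * y - 0.4 * x) + ph[3])
    )
    g = g / np.abs(g).max() if np.abs(g).max() > 0 else g
    return 1.0 + amplitude * g


def generate(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns (uint8 image, boolean ground-truth mask)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.dims
    head = _ellipse_mask(
        spec.dims,
        (h / 2.0, w / 2.0),
        (spec.head_axes[0] * h / 2.0, spec.head_axes[1] * w / 2.0),
        0.0,
    )
    target_pct = (
        spec.tumor_area_pct
        if spec.tumor_area_pct is not None
        else float(rng.uniform(2.5, 8.0))
    )
    target_px = target_pct / 100.0 * h * w
    per_blob = target_px / spec.tumor_count

    tumor = np.zeros((h, w), dtype=bool)
    for _ in range(spec.tumor_count):
        blob = _place_blob(spec.dims, head, tumor, per_blob, rng)
        tumor |= blob

    img = np.full((h, w), float(spec.background_intensity))
    img[head] = spec.tissue_intensity
    img[tumor] = spec.tumor_intensity
    img *= _bias_field(spec.dims, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        if spec.rician:
            # magnitude of a complex signal with iid Gaussian parts
            re = img + rng.normal(0, spec.noise_sigma, size=img.shape)
            im = rng.normal(0, spec.noise_sigma, size=img.shape)
            img = np.hypot(re, im)
        else:
            img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    achieved = 100.0 * tumor.sum() / tumor.size
    if abs(achieved - target_pct) > 0.5:
        raise InfeasibleSpec(
            f"lesion area {achieved:.2f}% misses target {target_pct:.2f}% by more than 0.5"
        )
    return img, tumor


def _place_blob(dims, head, existing, area_px, rng) -> np.ndarray:
    """Seat one elliptical lesion of ~area_px pixels fully inside the head."""
    h, w = dims
    for _ in range(200):
        aspect = rng.uniform(0.6, 1.0)
        # pi*a*b = area  with  b = aspect*a
        a = np.sqrt(area_px / (np.pi * aspect))
        b = aspect * a
        angle = rng.uniform(0, np.pi)
        cr = rng.uniform(0.25 * h, 0.75 * h)
        cc = rng.uniform(0.25 * w, 0.75 * w)
        blob = _ellipse_mask(dims, (cr, cc), (a, b), angle)
        if blob.any() and not (blob & ~head).any() and not (blob & existing).any():
            return blob
    raise InfeasibleSpec(f"could not place a lesion of {area_px:.0f} px inside the head")


def batch(
    template: PhantomSpec, n: int, base_seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """n deterministic phantoms with seeds base_seed .. base_seed + n - 1."""
    if n < 1:
        raise ValueError("need at least one phantom")
    out = []
    for k in range(n):
        from dataclasses import replace

        spec = replace(template, seed=base_seed + k)
        img, mask = generate(spec)
        out.append((img, mask, spec))
    return out
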