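"""Segmentation pipeline: Otsu seeding, region growing, RG-FCM, ROI cleanup."""

import numpy as np
import pytest

from rgscodec import phantom, seg_metrics, segmentation
from rgscodec.errors import (
    DegenerateHistogram,
    EmptyForeground,
    InvalidFuzzifier,
    SeedOutOfBounds,
)
from rgscodec.segmentation import (
    FcmState,
    SegmentationConfig,
    extract_roi,
    otsu_threshold,
    region_grow,
    rg_fcm,
    segment,
    select_seed,
)

from conftest import random_image


# ------------------------------------------------------------------ Otsu


def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive scan of all 256 thresholds maximizing between-class variance."""
    flat = img.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        bg = flat[flat <= t]
        fg = flat[flat > t]
        if len(bg) == 0 or len(fg) == 0:
            continue
        w0, w1 = len(bg) / len(flat), len(fg) / len(flat)
        v = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if v > best_v:  # strict: keeps smallest t on ties
            best_v, best_t = v, t
    return best_t


def test_otsu_constant_image_raises():
    with pytest.raises(DegenerateHistogram):
        otsu_threshold(np.full((16, 16), 100, np.uint8))


def test_otsu_separates_bimodal_exactly():
    img = np.full((20, 20), 50, np.uint8)
    img.ravel()[:160] = 200  # 40% at 200, 60% at 50
    t = otsu_threshold(img)
    assert 50 <= t < 200
    assert np.array_equal(img > t, img == 200)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_otsu_matches_exhaustive_scan(seed):
    img = random_image(seed)
    assert otsu_threshold(img) == brute_force_otsu(img)


# ------------------------------------------------------------------ seed


def test_seed_all_foreground_ties_to_first():
    img = np.zeros((8, 8), np.uint8)
    img[2, 5] = img[4, 1] = img[6, 6] = 180
    assert select_seed(img, 100) == (2, 5)


def test_seed_exact_mean_match():
    img = np.zeros((8, 8), np.uint8)
    img[1, 1], img[2, 2], img[3, 3] = 100, 150, 200
    assert select_seed(img, 50) == (2, 2)


def test_seed_empty_foreground_raises():
    with pytest.raises(EmptyForeground):
        select_seed(np.zeros((8, 8), np.uint8), 10)


@pytest.mark.parametrize("seed", [1, 11, 21])
def test_seed_matches_exhaustive_scan(seed):
    img = random_image(seed)
    t = 128
    fg = [(r, c) for r in range(32) for c in range(32) if img[r, c] > t]
    mean = np.mean([img[p] for p in fg])
    expected = min(fg, key=lambda p: (abs(float(img[p]) - mean), p[0] * 32 + p[1]))
    assert select_seed(img, t) == expected


# ---------------------------------------------------------- region growing


def reference_region_grow(img, seed, tol):
    """Second breadth-first implementation of the same admission rule,
    written list-style rather than deque-style."""
    h, w = img.shape
    region = {seed}
    tested = {seed}
    frontier = [seed]
    total = float(img[seed])
    order = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))
    while frontier:
        next_frontier = []
        for r, c in frontier:
            for dr, dc in order:
                p = (r + dr, c + dc)
                if 0 <= p[0] < h and 0 <= p[1] < w and p not in tested:
                    tested.add(p)
                    if abs(float(img[p]) - total / len(region)) <= tol:
                        region.add(p)
                        total += float(img[p])
                        next_frontier.append(p)
        frontier = next_frontier
    mask = np.zeros((h, w), bool)
    for p in region:
        mask[p] = True
    return mask


def test_region_grow_uniform_covers_all():
    img = np.full((12, 12), 77, np.uint8)
    res = region_grow(img, (5, 5), 0)
    assert res.mask.all()


def test_region_grow_isolated_block():
    img = np.zeros((32, 32), np.uint8)
    img[10:20, 10:20] = 200
    res = region_grow(img, (15, 15), 5)
    assert np.array_equal(res.mask, img == 200)


def test_region_grow_out_of_bounds():
    with pytest.raises(SeedOutOfBounds):
        region_grow(np.zeros((8, 8), np.uint8), (9, 0), 1)


def test_region_grow_matches_independent_bfs():
    r = np.random.default_rng(2)
    img = (120 + 30 * np.exp(-((np.arange(32)[:, None] - 16) ** 2 +
                               (np.arange(32)[None, :] - 16) ** 2) / 60.0)
           + r.normal(0, 4, (32, 32)))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    res = region_grow(img, (16, 16), 12)
    assert np.array_equal(res.mask, reference_region_grow(img, (16, 16), 12))


@pytest.mark.parametrize("seed", [5, 6])
def test_region_grow_single_component_contains_seed(seed):
    from scipy import ndimage

    img = random_image(seed)
    res = region_grow(img, (10, 10), 30)
    assert res.mask[10, 10]
    _, n = ndimage.label(res.mask, structure=np.ones((3, 3)))
    assert n == 1


# ------------------------------------------------------------------- FCM


def _rg_of(mask):
    from rgscodec.segmentation import RegionGrowResult

    seed = tuple(np.argwhere(mask)[0]) if mask.any() else (0, 0)
    return RegionGrowResult(mask=mask, seed=seed, region_mean=0.0, tolerance=0.0)


def test_fcm_separable_two_blocks():
    img = np.zeros((16, 16), np.uint8)
    img[:, 8:] = 255
    rg = _rg_of(img == 255)
    state = rg_fcm(img, rg, m=2, rng_seed=0)
    assert (np.max(state.U, axis=1) >= 0.999).all()
    intens = np.sort(state.V[:, 0])
    assert abs(intens[0] - 0) < 0.5 and abs(intens[1] - 255) < 0.5


def test_fcm_identical_points_degenerate():
    img = np.full((8, 8), 42, np.uint8)
    state = rg_fcm(img, _rg_of(np.zeros((8, 8), bool)), m=2, rng_seed=1)
    assert state.objective_trace[0] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(state.U.sum(axis=1), 1.0)


def test_fcm_invalid_fuzzifier():
    img = random_image(0, (16, 16))
    with pytest.raises(InvalidFuzzifier):
        rg_fcm(img, _rg_of(np.zeros((16, 16), bool)), p=1.0)


def reference_fcm(X, m, p, seed, iters):
    """Straight-from-formula FCM with the same seeded initialization."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    V = lo + (hi - lo) * rng.random((m, X.shape[1]))

    def memberships(V):
        U = np.zeros((len(X), m))
        for j, x in enumerate(X):
            d = [np.linalg.norm(x - V[i]) for i in range(m)]
            if any(di == 0 for di in d):
                U[j, d.index(0.0)] = 1.0
                continue
            for i in range(m):
                U[j, i] = 1.0 / sum((d[i] / d[k]) ** (2 / (p - 1)) for k in range(m))
        return U

    U = memberships(V)
    for _ in range(iters):
        for i in range(m):
            w = U[:, i] ** p
            V[i] = (w[:, None] * X).sum(axis=0) / w.sum()
        U = memberships(V)
    return U, V


def test_fcm_matches_direct_formula_reference():
    # 6 hand-listed 2-D feature points: (intensity, lambda*indicator)
    pts = np.array([[10.0, 0.0], [12.0, 0.0], [11.0, 0.0],
                    [200.0, 128.0], [205.0, 128.0], [198.0, 128.0]])
    from rgscodec.segmentation import _memberships

    U_ref, V_ref = reference_fcm(pts, m=2, p=2.0, seed=0, iters=25)
    # implementation route: same init, vectorized updates
    rng = np.random.default_rng(0)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    V = lo + (hi - lo) * rng.random((2, 2))
    U = _memberships(pts, V, 2.0)
    for _ in range(25):
        Up = U**2.0
        V = (Up.T @ pts) / Up.sum(axis=0)[:, None]
        U = _memberships(pts, V, 2.0)
    assert np.allclose(U, U_ref, atol=1e-6)
    assert np.allclose(V, V_ref, atol=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fcm_invariants_row_sums_and_objective(seed):
    img = random_image(seed, (24, 24))
    rg = _rg_of(img > 128)
    state = rg_fcm(img, rg, m=3, rng_seed=seed)
    assert np.allclose(state.U.sum(axis=1), 1.0, atol=1e-9)
    tr = state.objective_trace
    assert all(tr[k + 1] <= tr[k] + 1e-9 for k in range(len(tr) - 1))
    assert state.iterations <= 200


# ------------------------------------------------------------ ROI extraction


def test_extract_roi_separable_blocks():
    img = np.zeros((16, 16), np.uint8)
    img[:, 8:] = 255
    rg = _rg_of(img == 255)
    state = rg_fcm(img, rg, m=2, rng_seed=0)
    assert np.array_equal(extract_roi(state, img, rg), img == 255)


def test_extract_roi_uniform_membership_empty_rg():
    img = np.zeros((8, 8), np.uint8)
    state = FcmState(
        U=np.full((64, 2), 0.5), V=np.array([[0.0, 0.0], [0.0, 0.0]]), p=2.0, m=2
    )
    assert not extract_roi(state, img, _rg_of(np.zeros((8, 8), bool))).any()


def test_extract_roi_recovers_phantom_ground_truth(clean_phantom):
    img, gt = clean_phantom
    res = segment(img)
    assert np.array_equal(res.roi_mask, gt)


# ------------------------------------------------------------- full pipeline


def test_segment_noise_free_exact():
    img, gt = phantom.generate(phantom.PhantomSpec(seed=4, noise_sigma=0))
    assert np.array_equal(segment(img).roi_mask, gt)


def test_segment_constant_raises():
    with pytest.raises(DegenerateHistogram):
        segment(np.full((32, 32), 7, np.uint8))


def test_segment_noisy_phantom_overlap():
    img, gt = phantom.generate(phantom.PhantomSpec(seed=5, noise_sigma=10))
    res = segment(img)
    assert seg_metrics.jaccard(res.roi_mask, gt) >= 0.90


def test_segment_deterministic():
    img, _ = phantom.generate(phantom.PhantomSpec(seed=6, noise_sigma=8))
    a = segment(img, SegmentationConfig(seed=11))
    b = segment(img, SegmentationConfig(seed=11))
    assert np.array_equal(a.roi_mask, b.roi_mask)
    assert np.array_equal(a.fcm.U, b.fcm.U)
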