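"""Box-scan, fractal-dimension and lacunarity estimator tests.

The scan is checked against a brute-force per-box oracle (`naive_scan`)
that re-derives every box mass and differential term with explicit loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofrac import (
    BoxCountConfig,
    GrayscaleImage,
    build_scale_series,
    estimate_fd,
    estimate_lacunarity,
    generate_sierpinski_carpet,
    make_grids,
    profile_image,
    scan,
)
from mitofrac.fracdim import DegenerateImageError, EstimationError

LOG8_LOG3 = np.log(8) / np.log(3)


# --- independent oracle -----------------------------------------------------

def naive_scan(pixels, mask, scales, offsets, grayscale):
    """Brute-force reimplementation: explicit loops over boxes and pixels.

    Returns {(grid, eps): (sorted masses, sorted deltas or None, N)}.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    pixels = pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    mask = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    H, W = pixels.shape
    out = {}
    for g, (orr, occ) in enumerate(offsets):
        for eps in scales:
            o_r, o_c = int(orr) % eps, int(occ) % eps
            masses, deltas = [], []
            for r0 in range(o_r, H, eps):
                for c0 in range(o_c, W, eps):
                    vals, in_mask = [], 0
                    for r in range(r0, min(r0 + eps, H)):
                        for c in range(c0, min(c0 + eps, W)):
                            if mask[r, c]:
                                in_mask += 1
                                vals.append(pixels[r, c])
                    if in_mask == 0:
                        continue
                    masses.append(sum(1 for v in vals if v > 0))
                    deltas.append(max(vals) - min(vals) + 1.0)
            if grayscale:
                n = float(sum(deltas))
            else:
                n = float(sum(1 for m in masses if m > 0))
            out[(g, eps)] = (sorted(masses), sorted(deltas) if grayscale else None, n)
    return out


@pytest.mark.parametrize("mode", ["binary", "grayscale_differential"])
def test_scan_matches_bruteforce_oracle(rng, mode):
    """Vectorised scan reproduces a per-pixel double-loop box enumeration."""
    for trial in range(25):
        h, w = rng.integers(4, 33, 2)
        pixels = np.where(rng.random((h, w)) < 0.6, rng.integers(0, 9, (h, w)), 0).astype(float)
        if not pixels.any():
            pixels[0, 0] = 1.0
        mask = None
        if trial % 3 == 0:
            mask = rng.random((h, w)) < 0.7
            mask[int(rng.integers(h)), int(rng.integers(w))] = True
        img = GrayscaleImage(pixels, mask=mask)
        max_eps = min(h, w)
        n_scales = int(rng.integers(2, 5))
        scales = tuple(sorted(set(rng.integers(1, max_eps + 1, n_scales).tolist())))
        cfg = BoxCountConfig(
            n_grids=int(rng.integers(1, 5)), count_mode=mode,
            scales=scales, seed=int(rng.integers(10_000)),
        )
        result = scan(img, cfg)
        expected = naive_scan(
            img.pixels, img.effective_mask(), scales, result.offsets, mode != "binary"
        )
        for g in range(cfg.n_grids):
            for si, eps in enumerate(scales):
                cell = result.stats[g][si]
                masses_ref, deltas_ref, n_ref = expected[(g, eps)]
                assert sorted(cell.masses.tolist()) == masses_ref
                assert cell.n == n_ref
                if mode != "binary":
                    assert np.allclose(sorted(cell.deltas.tolist()), deltas_ref)


# --- scale series and grids -------------------------------------------------

def test_scale_series_default_ladder():
    series = build_scale_series((100, 100), BoxCountConfig())
    assert series[0] == 2 and series[-1] == 45
    assert series[:6] == [2, 3, 4, 5, 7, 9]
    assert all(b > a for a, b in zip(series, series[1:]))

def test_scale_series_respects_override_and_small_images():
    cfg = BoxCountConfig(scales=(1, 3, 9, 27))
    assert build_scale_series((81, 81), cfg) == [1, 3, 9, 27]
    with pytest.raises(EstimationError):
        build_scale_series((8, 8), BoxCountConfig())  # too few scales

def test_grids_deterministic_and_origin_anchored():
    cfg = BoxCountConfig(n_grids=12, seed=7)
    g1, g2 = make_grids(cfg), make_grids(cfg)
    assert np.array_equal(g1, g2)
    assert tuple(g1[0]) == (0, 0)
    assert len(make_grids(BoxCountConfig(n_grids=1))) == 1


# --- analytic fixtures -------------------------------------------------------

def test_sierpinski_counts_and_dimension():
    """Self-similar carpet: N(3^k) = 8^(level-k) on the origin grid, D = log8/log3."""
    img = generate_sierpinski_carpet(2)
    cfg = BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 3))
    res = scan(img, cfg)
    assert [s.n for s in res.stats[0]] == [64.0, 8.0]

    lvl4 = generate_sierpinski_carpet(4)
    cfg4 = BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 3, 9, 27))
    est = estimate_fd(scan(lvl4, cfg4))
    assert est.dimension == pytest.approx(LOG8_LOG3, abs=1e-9)
    assert est.per_grid_r2[0] == pytest.approx(1.0, abs=1e-12)

def test_filled_square_dimension_two_and_zero_lacunarity():
    img = GrayscaleImage(np.ones((64, 64)))
    cfg = BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 2, 4, 8, 16))
    res = scan(img, cfg)
    assert estimate_fd(res).dimension == pytest.approx(2.0, abs=1e-9)
    assert estimate_lacunarity(res).lacunarity == 0.0

def test_single_pixel_dimension_zero():
    px = np.zeros((32, 32))
    px[5, 7] = 3.0
    res = scan(GrayscaleImage(px), BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 2, 4, 8)))
    assert estimate_fd(res).dimension == pytest.approx(0.0, abs=1e-12)

def test_all_zero_image_rejected():
    with pytest.raises(DegenerateImageError):
        scan(GrayscaleImage(np.zeros((16, 16))), BoxCountConfig(scales=(1, 2, 4, 8)))

def test_constant_image_grayscale_deltas_are_one():
    """max = min in every box, so each differential term is exactly 1."""
    img = GrayscaleImage(np.full((12, 12), 7.0))
    res = scan(img, BoxCountConfig(n_grids=1, scales=(2, 3, 4)))
    for si, eps in enumerate(res.scales):
        cell = res.stats[0][si]
        assert np.all(cell.deltas == 1.0)
        assert cell.n == (12 // eps) ** 2

def test_checkerboard_differential_enumeration():
    """4x4 checkerboard of 0/100: every aligned 2x2 box spans the full range."""
    cb = (np.indices((4, 4)).sum(axis=0) % 2 * 100).astype(float)
    res = scan(GrayscaleImage(cb), BoxCountConfig(n_grids=1, scales=(1, 2)))
    assert [s.n for s in res.stats[0]] == [16.0, 404.0]


# --- lacunarity --------------------------------------------------------------

def test_quadrant_lacunarity_enumeration(quadrant_image):
    """Masses {16,0,0,0} at eps=4: mu=4, sigma^2=48, lambda=3."""
    cfg = BoxCountConfig(n_grids=1, count_mode="binary", scales=(1, 2, 4))
    lac = estimate_lacunarity(scan(quadrant_image, cfg))
    assert lac.lambda_by_scale_grid[2, 0] == pytest.approx(3.0)

def test_lacunarity_orders_clustered_above_dispersed(rng):
    """At equal point density, clustered mass is gappier than dispersed mass."""
    dispersed = np.zeros((64, 64))
    dispersed[::4, ::4] = 1.0  # 256 points, evenly spread
    clustered = np.zeros((64, 64))
    clustered[:16, :16] = 1.0  # same 256 points, one block
    cfg = BoxCountConfig(seed=0, count_mode="binary")
    lam_d = estimate_lacunarity(scan(GrayscaleImage(dispersed), cfg)).lacunarity
    lam_c = estimate_lacunarity(scan(GrayscaleImage(clustered), cfg)).lacunarity
    assert lam_c > lam_d

def test_uniform_field_lacunarity_decreases_with_scale_and_density(rng):
    """Box-mass averaging shrinks lambda with eps (aligned dividing scales,
    where every box holds the same pixel count); a full field has lambda ~ 0."""
    field = (rng.random((64, 64)) < 0.3).astype(float)
    cfg = BoxCountConfig(n_grids=1, count_mode="binary", scales=(2, 4, 8, 16))
    lac = estimate_lacunarity(scan(GrayscaleImage(field), cfg))
    by_scale = lac.by_scale()
    assert np.all(np.diff(by_scale) < 0)
    dense = (rng.random((64, 64)) < 0.999).astype(float)
    lac_dense = estimate_lacunarity(scan(GrayscaleImage(dense), cfg))
    assert lac_dense.lacunarity < 0.01


# --- masking and profiles -----------------------------------------------------

def test_masked_profile_equals_cropped_profile(rng):
    """A rectangular ROI behaves exactly like cropping to its bounding box."""
    sub = rng.uniform(0, 100, (40, 50))
    big = np.zeros((100, 100))
    big[20:60, 30:80] = sub
    mask = np.zeros((100, 100), dtype=bool)
    mask[20:60, 30:80] = True
    cfg = BoxCountConfig(seed=3)
    p_masked = profile_image(GrayscaleImage(big, mask=mask), cfg)
    p_cropped = profile_image(GrayscaleImage(sub), cfg)
    assert p_masked.fd == p_cropped.fd
    assert p_masked.lacunarity == p_cropped.lacunarity

def test_profile_deterministic(rng):
    img = GrayscaleImage(rng.uniform(0, 50, (64, 64)))
    cfg = BoxCountConfig(seed=9)
    p1, p2 = profile_image(img, cfg), profile_image(img, cfg)
    assert p1.fd == p2.fd and p1.lacunarity == p2.lacunarity


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_binary_dimension_bounded_for_2d_images(seed):
    """Binary box-counting dimension of any 2-D image stays within [0, 2]."""
    r = np.random.default_rng(seed)
    px = (r.random((32, 32)) < r.uniform(0.05, 0.95)).astype(float)
    if not px.any():
        px[0, 0] = 1.0
    cfg = BoxCountConfig(n_grids=3, count_mode="binary", scales=(1, 2, 4, 8), seed=seed % 1000)
    d = estimate_fd(scan(GrayscaleImage(px), cfg)).dimension
    assert -0.05 <= d <= 2.05  # small tolerance for regression noise
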