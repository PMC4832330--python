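"""Box-counting fractal dimension and gliding-grid lacunarity.

The estimator tiles an image with square boxes of increasing size from
several translated grid positions. In **binary** mode each scale contributes
the number of boxes containing foreground; in **grayscale differential**
mode each box contributes its intensity range plus one, so the scan responds
to texture and not just occupancy. The fractal dimension is the negative
slope of the ordinary least-squares fit of ln N(eps) against ln eps,
averaged over grid positions. Lacunarity is the squared coefficient of
variation of the per-box foreground-pixel masses, averaged over scales and
grids — high values mean gappy, clumped mass; zero means translation-uniform
mass.

Default protocol: box sizes from 2 px up to 45% of the shorter image side on
a geometric ladder, 12 grid positions (one anchored at the origin, the rest
at seeded random offsets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as _sps

from .imageprep import GrayscaleImage

__all__ = [
    "BoxCountConfig",
    "BoxCountScan",
    "GridScaleStats",
    "FractalEstimate",
    "LacunarityEstimate",
    "FractalProfile",
    "DegenerateImageError",
    "EstimationError",
    "build_scale_series",
    "make_grids",
    "scan",
    "estimate_fd",
    "estimate_lacunarity",
    "profile_image",
]


class DegenerateImageError(ValueError):
    """The image carries no usable foreground signal."""


class EstimationError(ValueError):
    """Too few valid scales or grids to fit a scaling exponent."""


@dataclass(frozen=True)
class BoxCountConfig:
    """Protocol parameters for a multi-grid box scan.

    Parameters
    ----------
    min_box : smallest box side in pixels.
    max_box_fraction : largest box side as a fraction of the shorter image
        side.
    n_grids : number of grid positions; grid 0 is anchored at the origin,
        the others at seeded uniform offsets.
    scale_ratio : multiplicative step of the box-size ladder.
    seed : RNG seed for the grid offsets.
    count_mode : "grayscale_differential" (intensity range + 1 per box) or
        "binary" (occupied-box count).
    scales : explicit box sizes overriding the generated ladder.
    """

    min_box: int = 2
    max_box_fraction: float = 0.45
    n_grids: int = 12
    scale_ratio: float = 1.3
    seed: int = 0
    count_mode: Literal["grayscale_differential", "binary"] = "grayscale_differential"
    scales: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.min_box < 1:
            raise ValueError("min_box must be >= 1")
        if not 0 < self.max_box_fraction < 1:
            raise ValueError("max_box_fraction must be in (0, 1)")
        if self.n_grids < 1:
            raise ValueError("n_grids must be >= 1")
        if self.scale_ratio <= 1:
            raise ValueError("scale_ratio must be > 1")
        if self.count_mode not in ("grayscale_differential", "binary"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.scales is not None:
            sc = tuple(int(s) for s in self.scales)
            if any(s < 1 for s in sc) or list(sc) != sorted(set(sc)):
                raise ValueError("explicit scales must be strictly increasing positive ints")
            object.__setattr__(self, "scales", sc)


def build_scale_series(image_shape: tuple[int, int], config: BoxCountConfig) -> list[int]:
    """Box-size ladder for an image: geometric series, capped at the maximum.

    Sizes follow ``eps_{k+1} = round(eps_k * scale_ratio)`` (at least +1 per
    step), starting at ``min_box`` and capped at
    ``floor(max_box_fraction * min(H, W))``; the cap itself closes the series.
    Explicit ``config.scales`` are accepted verbatim.
    """
    if config.scales is not None:
        return list(config.scales)
    short = min(image_shape)
    max_box = int(np.floor(config.max_box_fraction * short))
    if config.min_box > max_box:
        raise EstimationError(
            f"min_box {config.min_box} exceeds the largest allowed box {max_box}"
        )
    series = [config.min_box]
    while True:
        nxt = max(series[-1] + 1, int(np.floor(series[-1] * config.scale_ratio + 0.5)))
        if nxt >= max_box:
            if max_box > series[-1]:
                series.append(max_box)
            break
        series.append(nxt)
    if len(series) < 4:
        raise EstimationError(
            f"image of shape {image_shape} supports only {len(series)} scales (need >= 4)"
        )
    return series


def make_grids(config: BoxCountConfig) -> np.ndarray:
    """Grid translation offsets, shape (n_grids, 2).

    Grid 0 sits at the origin; the rest get one seeded uniform offset pair
    each, applied modulo the box size at every scale.
    """
    offsets = np.zeros((config.n_grids, 2), dtype=np.int64)
    if config.n_grids > 1:
        rng = np.random.default_rng(config.seed)
        offsets[1:] = rng.integers(0, 1_000_000, size=(config.n_grids - 1, 2))
    return offsets


@dataclass(frozen=True)
class GridScaleStats:
    """Per-box statistics for one (grid, scale) cell of a scan.

    `masses` holds the positive-pixel count of every box that contains at
    least one in-mask pixel (zeros included — empty but in-mask boxes carry
    information for lacunarity). `deltas` holds the per-box differential
    terms (intensity range + 1) in grayscale mode, and is None in binary
    mode. `n` is the scale's box-count statistic N(eps).
    """

    masses: np.ndarray
    deltas: np.ndarray | None
    n: float


@dataclass(frozen=True)
class BoxCountScan:
    """All per-(grid, scale) box statistics of one image."""

    scales: tuple[int, ...]
    offsets: np.ndarray  # (n_grids, 2)
    count_mode: str
    stats: tuple[tuple[GridScaleStats, ...], ...]  # [grid][scale]
    config: BoxCountConfig

    @property
    def n_grids(self) -> int:
        return len(self.stats)


def _box_stats(pixels, mask, eps, off_r, off_c, grayscale):
    """Vectorised per-box statistics for one grid offset and box size.

    The grid is anchored at (off_r mod eps, off_c mod eps): boxes tile
    forward from the anchor, trailing partial boxes at the far borders are
    kept (they are padded with out-of-mask pixels to full eps x eps tiles of
    a 4-D reshape), and the thin strip before the anchor lies outside this
    grid position. Extending the grid backwards instead would add a second
    partial box per axis and systematically inflate N at scales comparable
    to the image, biasing the dimension low.
    """
    o_r, o_c = off_r % eps, off_c % eps
    px = pixels[o_r:, o_c:]
    mk = mask[o_r:, o_c:]
    if px.size == 0:
        return np.empty(0), (np.empty(0) if grayscale else None), 0.0
    H, W = px.shape
    pad_b = (-H) % eps
    pad_r = (-W) % eps
    px = np.pad(px, ((0, pad_b), (0, pad_r)))
    mk = np.pad(mk, ((0, pad_b), (0, pad_r)))
    nr, nc = px.shape[0] // eps, px.shape[1] // eps
    px4 = px.reshape(nr, eps, nc, eps)
    mk4 = mk.reshape(nr, eps, nc, eps)

    in_mask = mk4.sum(axis=(1, 3))
    masses = (mk4 & (px4 > 0)).sum(axis=(1, 3))
    valid = in_mask > 0
    if grayscale:
        mx = np.where(mk4, px4, -np.inf).max(axis=(1, 3))
        mn = np.where(mk4, px4, np.inf).min(axis=(1, 3))
        deltas = (mx - mn + 1.0)[valid]
        n = float(deltas.sum())
    else:
        deltas = None
        n = float(np.count_nonzero(masses[valid]))
    return masses[valid].astype(float), deltas, n


def scan(img: GrayscaleImage, config: BoxCountConfig | None = None) -> BoxCountScan:
    """Tile the (masked) image with boxes at every scale and grid position.

    Per box the scan records the positive-pixel mass and, in grayscale mode,
    the differential term delta = (max - min intensity over in-mask pixels)
    + 1; N(eps) sums the deltas (grayscale) or counts occupied boxes
    (binary). Boxes wholly outside the mask are dropped.
    """
    config = config or BoxCountConfig()
    pixels = img.pixels
    mask = img.effective_mask()
    if not np.any((pixels > 0) & mask):
        raise DegenerateImageError("image has no positive in-mask pixel")
    # Grids anchor at the mask's bounding box, so the profile of a masked
    # image equals the profile of the image cropped to that rectangle.
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    pixels = pixels[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    scales = build_scale_series(pixels.shape, config)
    offsets = make_grids(config)
    grayscale = config.count_mode == "grayscale_differential"

    stats = tuple(
        tuple(
            GridScaleStats(*_box_stats(pixels, mask, eps, int(o_r), int(o_c), grayscale))
            for eps in scales
        )
        for o_r, o_c in offsets
    )
    return BoxCountScan(tuple(scales), offsets, config.count_mode, stats, config)


@dataclass(frozen=True)
class FractalEstimate:
    """Box-counting dimension: per-grid slopes and their mean."""

    per_grid_dimension: tuple[float, ...]
    per_grid_r2: tuple[float, ...]
    dimension: float
    excluded_grids: tuple[int, ...]
    config: BoxCountConfig


@dataclass(frozen=True)
class LacunarityEstimate:
    """Gliding-grid lacunarity: per (scale, grid) values and their mean."""

    lambda_by_scale_grid: np.ndarray  # (n_scales, n_grids), NaN where undefined
    lacunarity: float
    scales: tuple[int, ...]
    excluded_cells: tuple[tuple[int, int], ...]  # (scale index, grid index)
    config: BoxCountConfig

    def by_scale(self) -> np.ndarray:
        """Grid-averaged lacunarity per scale (alternative reduction)."""
        return np.nanmean(self.lambda_by_scale_grid, axis=1)


@dataclass(frozen=True)
class FractalProfile:
    """Joint fractal dimension + lacunarity profile of one image."""

    fractal: FractalEstimate
    lacunarity_estimate: LacunarityEstimate

    @property
    def fd(self) -> float:
        return self.fractal.dimension

    @property
    def lacunarity(self) -> float:
        return self.lacunarity_estimate.lacunarity


def estimate_fd(box_scan: BoxCountScan) -> FractalEstimate:
    """Fractal dimension from the log-log regression of N(eps) on eps.

    Per grid, D_g is minus the OLS slope of ln N over ln eps across scales
    with N > 0; grids with fewer than 3 usable scales are excluded from the
    mean and reported. The dimension is the arithmetic mean of the D_g.
    """
    dims, r2s, excluded = [], [], []
    log_eps_all = np.log(np.asarray(box_scan.scales, dtype=float))
    for g, per_scale in enumerate(box_scan.stats):
        n = np.array([s.n for s in per_scale])
        ok = n > 0
        if ok.sum() < 3:
            excluded.append(g)
            continue
        res = _sps.linregress(log_eps_all[ok], np.log(n[ok]))
        dims.append(-res.slope)
        r2s.append(res.rvalue**2)
    if not dims:
        raise EstimationError("no grid offers >= 3 scales with N > 0")
    return FractalEstimate(
        per_grid_dimension=tuple(dims),
        per_grid_r2=tuple(r2s),
        dimension=float(np.mean(dims)),
        excluded_grids=tuple(excluded),
        config=box_scan.config,
    )


def estimate_lacunarity(box_scan: BoxCountScan) -> LacunarityEstimate:
    """Lacunarity from the per-box positive-pixel masses.

    Per (scale, grid) cell, lambda = (sigma / mu)^2 over the box masses
    (population variance, boxes intersecting the mask only). Cells with zero
    mean mass are excluded and flagged. The summary is the mean of lambda
    over all defined cells.
    """
    n_scales, n_grids = len(box_scan.scales), box_scan.n_grids
    lam = np.full((n_scales, n_grids), np.nan)
    excluded = []
    for g, per_scale in enumerate(box_scan.stats):
        for s, cell in enumerate(per_scale):
            mu = cell.masses.mean() if cell.masses.size else 0.0
            if mu == 0:
                excluded.append((s, g))
                continue
            lam[s, g] = cell.masses.var() / mu**2
    if np.all(np.isnan(lam)):
        raise DegenerateImageError("zero total mass at every scale")
    return LacunarityEstimate(
        lambda_by_scale_grid=lam,
        lacunarity=float(np.nanmean(lam)),
        scales=box_scan.scales,
        excluded_cells=tuple(excluded),
        config=box_scan.config,
    )


def profile_image(img: GrayscaleImage, config: BoxCountConfig | None = None) -> FractalProfile:
    """One scan driving both estimators, for a prepared (projected,
    background-subtracted, masked) image."""
    box_scan = scan(img, config)
    return FractalProfile(estimate_fd(box_scan), estimate_lacunarity(box_scan))
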