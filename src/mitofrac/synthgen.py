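"""Synthetic data generators for every stage of the morphometry pipeline.

Provides (a) deterministic fractals of known dimension (Sierpinski carpet,
fractional Brownian surfaces) to validate the box-counting estimators,
(b) simulated confocal images of mitochondrial networks spanning the
elongated/reticulated-to-fragmented/perinuclear morphology spectrum,
(c) dose-response plates with known EC50, (d) stress-test flux traces, and
(e) two-class cohorts and multi-cell-line panels for ROC and correlation
analyses. Every generator is a pure function of its parameters, including
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .imageprep import GrayscaleImage

__all__ = [
    "MorphologyParams",
    "DoseResponsePlateParams",
    "CohortParams",
    "ELONGATED_RETICULATED",
    "FRAGMENTED_PERINUCLEAR",
    "generate_sierpinski_carpet",
    "generate_brownian_surface",
    "generate_mito_image",
    "generate_dose_response",
    "generate_flux_trace",
    "generate_cohort",
    "generate_cell_line_panel",
    "four_pl",
]


# --- deterministic fractals ----------------------------------------------

def generate_sierpinski_carpet(level: int) -> GrayscaleImage:
    """Binary Sierpinski carpet of side 3**level.

    A pixel is foreground iff no base-3 digit pair of its (row, col)
    coordinates is (1, 1); the foreground count is exactly 8**level and the
    box-counting dimension is log 8 / log 3.
    """
    if not 1 <= level <= 6:
        raise ValueError("level must be in 1..6")
    side = 3**level
    idx = np.arange(side)
    keep = np.ones((side, side), dtype=bool)
    for k in range(level):
        digit = (idx // 3**k) % 3
        keep &= ~((digit[:, None] == 1) & (digit[None, :] == 1))
    return GrayscaleImage(keep.astype(float))


def generate_brownian_surface(
    hurst: float, size: int = 257, seed: int = 0, peak: float = 255.0
) -> GrayscaleImage:
    """Fractional Brownian surface by spectral synthesis.

    White noise is filtered in Fourier space with amplitude ~ f^-(hurst + 1),
    giving a random surface of theoretical dimension 3 - hurst; the result is
    rescaled to [0, peak]. Lower Hurst exponents give rougher textures and a
    higher grayscale-differential fractal dimension.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    n = int(2 ** math.ceil(math.log2(size)))
    fr = np.fft.fftfreq(n)
    f = np.hypot(fr[:, None], fr[None, :])
    f[0, 0] = 1.0  # avoid the DC singularity; DC amplitude is irrelevant after rescale
    amplitude = f ** (-(hurst + 1.0))
    phase = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    surface = np.real(np.fft.ifft2(phase * amplitude))[:size, :size]
    surface -= surface.min()
    if surface.max() > 0:
        surface *= peak / surface.max()
    return GrayscaleImage(surface)


# --- mitochondrial network images ----------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of a synthetic mitochondrial-network image.

    Tubules are persistent random walks: `persistence` in [0, 1] is the
    directional correlation of successive steps (1 = straight). In
    `perinuclear` mode tubules start inside the annulus
    [annulus_inner, annulus_outer] around the image centre and are reflected
    at its borders. Intensities sit on a constant `background_level` (as a
    detector offset would) with additive Gaussian noise, clipped at zero.
    """

    n_segments: int = 12
    mean_segment_length: float = 120.0  # pixels of path length
    persistence: float = 0.95
    tubule_width: float = 4.0  # pixels
    spatial_mode: str = "uniform"  # or "perinuclear"
    annulus_inner: float = 12.0
    annulus_outer: float = 40.0
    peak_intensity: float = 20000.0
    background_level: float = 600.0
    noise_sd: float = 100.0
    image_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spatial_mode not in ("uniform", "perinuclear"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        if self.spatial_mode == "perinuclear":
            if not (0 < self.annulus_inner < self.annulus_outer < self.image_size / 2):
                raise ValueError("annulus must satisfy 0 < inner < outer < image_size/2")


#: Archetype presets for the two ends of the morphology spectrum seen in
#: mesothelial cells: control-like elongated/reticulated networks spread
#: through the cytoplasm vs fragmented mitochondria condensed around the
#: nucleus. These are phenotype archetypes, not replicas of any cell line.
ELONGATED_RETICULATED = MorphologyParams(
    n_segments=12, mean_segment_length=120, persistence=0.95, spatial_mode="uniform"
)
FRAGMENTED_PERINUCLEAR = MorphologyParams(
    n_segments=150, mean_segment_length=8, persistence=0.6, spatial_mode="perinuclear"
)  # tight annulus: fragments condense into a compact perinuclear ring


def _fold(x, lo, hi):
    """Reflect coordinates into [lo, hi] (mirror/fold boundary condition)."""
    span = hi - lo
    t = np.mod(x - lo, 2.0 * span)
    return lo + np.minimum(t, 2.0 * span - t)


def generate_mito_image(params: MorphologyParams) -> GrayscaleImage:
    """Render one synthetic confocal field of a mitochondrial network.

    Each tubule is a persistent random walk (unit steps, turning angles
    ~ N(0, (1 - persistence) * pi)) drawn as a thick polyline, blurred with
    a Gaussian of sigma = tubule_width / 2 to emulate the microscope
    point-spread function, then scaled to peak_intensity and offset by the
    background level plus Gaussian noise (clipped at zero). Walks leaving
    the image (uniform mode) or the perinuclear annulus are reflected back
    by mirror-folding the offending coordinate.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    center = size / 2.0
    canvas = np.zeros((size, size), dtype=bool)
    turn_sd = (1.0 - params.persistence) * np.pi

    for _ in range(params.n_segments):
        if params.spatial_mode == "perinuclear":
            r0 = rng.uniform(params.annulus_inner, params.annulus_outer)
            theta0 = rng.uniform(0, 2 * np.pi)
            start = center + r0 * np.array([np.cos(theta0), np.sin(theta0)])
        else:
            start = rng.uniform(0, size - 1, size=2)
        n_steps = max(2, int(rng.poisson(params.mean_segment_length)))
        angles = rng.uniform(0, 2 * np.pi) + np.cumsum(rng.normal(0.0, turn_sd, n_steps))
        path = start + np.cumsum(
            np.column_stack([np.cos(angles), np.sin(angles)]), axis=0
        )
        path = np.vstack([start, path])
        if params.spatial_mode == "perinuclear":
            rel = path - center
            radius = np.hypot(rel[:, 0], rel[:, 1])
            folded = _fold(radius, params.annulus_inner, params.annulus_outer)
            with np.errstate(invalid="ignore"):
                scale = np.where(radius > 0, folded / np.maximum(radius, 1e-9), 0.0)
            path = center + rel * scale[:, None]
        path = _fold(path, 0.0, size - 1.0)
        pts = np.rint(path).astype(int)  # unit steps: successive pixels stay adjacent
        canvas[pts[:, 0], pts[:, 1]] = True

    radius = max(1, int(round(params.tubule_width / 2)))
    canvas = binary_dilation(canvas, structure=disk(radius).astype(bool))
    img = gaussian_filter(canvas.astype(float), sigma=params.tubule_width / 2)
    if img.max() > 0:
        img *= params.peak_intensity / img.max()
    img += params.background_level
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return GrayscaleImage(np.clip(img, 0.0, None))


# --- dose-response plates -------------------------------------------------

def four_pl(dose, ec50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic viability curve, decreasing for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


@dataclass(frozen=True)
class DoseResponsePlateParams:
    """Generative model of one cytotoxicity plate (per compound).

    Viability follows a four-parameter logistic in dose; well signals are
    vehicle_signal_mean * viability / 100 plus Gaussian noise. Six
    replicates per concentration mirror a standard 96-well design.
    """

    true_ec50: float = 10.0
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    doses: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
    n_replicates: int = 6
    noise_sd: float = 5.0  # percent-viability units
    vehicle_signal_mean: float = 50000.0
    compound: str = "compound"
    seed: int = 0

    def __post_init__(self):
        d = tuple(float(x) for x in self.doses)
        if any(x <= 0 for x in d) or list(d) != sorted(d):
            raise ValueError("doses must be strictly positive and sorted")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "doses", d)


def generate_dose_response(params: DoseResponsePlateParams) -> pd.DataFrame:
    """Simulate raw well signals for one compound's dose series.

    Returns a tidy table with columns (compound, dose, replicate, signal,
    is_vehicle); vehicle wells carry dose 0 and the undiminished signal.
    """
    rng = np.random.default_rng(params.seed)
    sd_signal = params.vehicle_signal_mean * params.noise_sd / 100.0
    rows = []
    for rep in range(params.n_replicates):
        noise = rng.normal(0.0, sd_signal) if params.noise_sd > 0 else 0.0
        rows.append((params.compound, 0.0, rep, max(params.vehicle_signal_mean + noise, 0.0), True))
    for dose in params.doses:
        v = four_pl(dose, params.true_ec50, params.hill, params.top, params.bottom)
        mean_signal = params.vehicle_signal_mean * v / 100.0
        for rep in range(params.n_replicates):
            noise = rng.normal(0.0, sd_signal) if params.noise_sd > 0 else 0.0
            rows.append((params.compound, dose, rep, max(mean_signal + noise, 0.0), False))
    return pd.DataFrame(rows, columns=["compound", "dose", "replicate", "signal", "is_vehicle"])


# --- extracellular-flux traces -------------------------------------------

def generate_flux_trace(
    basal_ocr: float = 100.0,
    max_ocr: float = 180.0,
    post_oligo_frac: float = 0.35,
    post_rotenone_frac: float = 0.1,
    basal_ecar: float = 40.0,
    protein: float = 10.0,
    noise_sd: float = 0.0,
    n_per_phase: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Simulate a mitochondrial stress test (raw, non-normalised rates).

    Four measurement cycles per phase: baseline, then oligomycin (ATP-synthase
    block drops OCR), FCCP (uncoupling raises OCR to its maximum), rotenone
    (complex I block collapses OCR). Returns (trace table, protein per well).
    """
    rng = np.random.default_rng(seed)
    phases = {
        "baseline": (basal_ocr, basal_ecar),
        "oligomycin": (basal_ocr * post_oligo_frac, basal_ecar * 1.3),
        "fccp": (max_ocr, basal_ecar * 1.1),
        "rotenone": (basal_ocr * post_rotenone_frac, basal_ecar),
    }
    rows = []
    cycle = 0
    for phase, (ocr, ecar) in phases.items():
        for _ in range(n_per_phase):
            cycle += 1
            o = ocr + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            e = ecar + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((cycle, phase, max(o, 0.0), max(e, 0.0)))
    return pd.DataFrame(rows, columns=["cycle", "phase", "ocr", "ecar"]), protein


# --- cohorts and panels ---------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Two-or-more-group normal score model feeding the ROC analysis."""

    group_means: tuple[float, ...] = (0.0, 1.0)
    group_sds: tuple[float, ...] = (1.0, 1.0)
    group_ns: tuple[int, ...] = (50, 50)
    group_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        k = len(self.group_means)
        if len(self.group_sds) != k or len(self.group_ns) != k:
            raise ValueError("group_means, group_sds, group_ns must have equal length")
        if any(n < 2 for n in self.group_ns):
            raise ValueError("each group needs n >= 2")
        if any(s <= 0 for s in self.group_sds):
            raise ValueError("group sds must be positive")
        if self.group_labels is None:
            object.__setattr__(
                self, "group_labels", tuple(f"group{i}" for i in range(k))
            )
        elif len(self.group_labels) != k:
            raise ValueError("group_labels length mismatch")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw labelled scores: columns (label, score)."""
    rng = np.random.default_rng(params.seed)
    frames = []
    for label, mu, sd, n in zip(
        params.group_labels, params.group_means, params.group_sds, params.group_ns
    ):
        frames.append(pd.DataFrame({"label": label, "score": rng.normal(mu, sd, n)}))
    return pd.concat(frames, ignore_index=True)


def _interp_morphology(m: float, image_size: int, seed: int) -> MorphologyParams:
    """Morphology archetype interpolated by fragmentation level m in [0, 1].

    Tubules shorten and multiply with m while their admissible region — an
    annulus around the nucleus — shrinks continuously from nearly the whole
    field (reticulated, distributed) to a tight perinuclear ring, so every
    morphology descriptor varies smoothly along the spectrum.
    """
    m = float(np.clip(m, 0.0, 1.0))
    return MorphologyParams(
        n_segments=int(round(12 + m * (150 - 12))),
        mean_segment_length=120 + m * (8 - 120),
        persistence=0.95 + m * (0.6 - 0.95),
        spatial_mode="perinuclear",
        annulus_inner=(0.030 + 0.017 * m) * image_size,
        annulus_outer=(0.480 - 0.324 * m) * image_size,
        image_size=image_size,
        seed=seed,
    )


def generate_cell_line_panel(
    n_lines: int = 8,
    link_strength: float = 1.0,
    seed: int = 0,
    n_cells_per_line: int = 40,
    image_size: int = 128,
    compound: str = "inhibitor",
    noise_sd_viability: float = 3.0,
) -> tuple[dict[str, list[GrayscaleImage]], dict[str, pd.DataFrame], pd.DataFrame]:
    """End-to-end synthetic study: cell-line images, plates, and ground truth.

    Per line a fragmentation level m ~ U(0, 1) is drawn; images become more
    fragmented/perinuclear as m grows, and the true log10 EC50 decreases
    linearly in m (fragmented lines are more inhibitor-sensitive) plus
    Gaussian noise scaled by (1 - link_strength). Returns
    (images per line, raw plate table per line, truth table with m and EC50).
    """
    if n_lines < 4:
        raise ValueError("n_lines must be >= 4")
    rng = np.random.default_rng(seed)
    m_values = rng.uniform(0.0, 1.0, n_lines)
    # true EC50 falls linearly from 70 to 7 concentration units across the
    # morphology spectrum (a ~10x span, as mitochondrial inhibitors show
    # between resistant and sensitive lines); the sensitivity driver blends
    # the line's fragmentation with independent noise weighted by
    # (1 - link_strength), so link 1 couples EC50 perfectly to morphology
    # and link 0 decouples it entirely
    driver = link_strength * m_values + (1.0 - link_strength) * rng.uniform(0.0, 1.0, n_lines)
    ec50_values = np.clip(70.0 - 63.0 * driver, 2.0, None)

    images: dict[str, list[GrayscaleImage]] = {}
    plates: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for i in range(n_lines):
        label = f"line{i:02d}"
        cell_seeds = rng.integers(0, 2**31 - 1, n_cells_per_line)
        images[label] = [
            generate_mito_image(_interp_morphology(m_values[i], image_size, int(s)))
            for s in cell_seeds
        ]
        ec50 = float(ec50_values[i])
        doses = tuple(np.round(ec50 * np.logspace(-2, 2, 8), 10))
        plates[label] = generate_dose_response(
            DoseResponsePlateParams(
                true_ec50=ec50,
                doses=doses,
                noise_sd=noise_sd_viability,
                compound=compound,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        truth_rows.append((label, float(m_values[i]), ec50))
    truth = pd.DataFrame(truth_rows, columns=["line", "fragmentation", "true_ec50"])
    return images, plates, truth
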