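"""Image preparation for fractal morphometry.

Confocal z-stacks of immunofluorescently labelled mitochondria are reduced
to a single maximum-intensity projection, a constant background level is
subtracted (clipping at zero so that "positive pixel" is well defined), and
an optional region-of-interest mask restricts all downstream box statistics
to the selected cell. Colour histology images are converted to luminance
grayscale before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "GrayscaleImage",
    "max_projection",
    "subtract_background",
    "to_grayscale",
    "apply_roi",
    "binarize",
    "invert_intensity",
    "read_image",
    "read_stack",
    "read_mask",
    "write_image",
    "DEFAULT_BACKGROUND",
]

#: Constant background level subtracted in the confocal workflow.
DEFAULT_BACKGROUND = 1000.0

#: Rec. 601 luminance weights for RGB -> grayscale conversion.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ImageStack:
    """An ordered z-stack of equally shaped, nonnegative intensity planes."""

    pages: tuple[np.ndarray, ...]
    bit_depth: int = 16
    pixel_size: float | None = None  # microns per pixel, if known

    def __post_init__(self):
        if len(self.pages) == 0:
            raise ValueError("stack must contain at least one page")
        pages = tuple(np.asarray(p, dtype=float) for p in self.pages)
        shape = pages[0].shape
        for p in pages:
            if p.ndim != 2:
                raise ValueError("every page must be a 2-D array")
            if p.shape != shape:
                raise ValueError("all pages must share one shape")
            if np.any(p < 0):
                raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "pages", pages)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pages[0].shape


@dataclass(frozen=True)
class GrayscaleImage:
    """2-D nonnegative intensity array with an optional binary ROI mask.

    The mask marks the pixels that belong to the analysed object (e.g. the
    mitochondrial network of one cell); box scans ignore boxes lying wholly
    outside it.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if np.any(px < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "pixels", px)
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.shape != px.shape:
                raise ValueError("mask shape must match pixels")
            if not m.any():
                raise ValueError("mask must contain at least one true pixel")
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def effective_mask(self) -> np.ndarray:
        """The mask, or an all-true array when no mask is attached."""
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask


def max_projection(stack: ImageStack) -> GrayscaleImage:
    """Collapse a z-stack into its per-pixel maximum-intensity projection."""
    if not isinstance(stack, ImageStack):
        stack = ImageStack(tuple(stack))
    proj = np.maximum.reduce(stack.pages)
    return GrayscaleImage(proj)


def subtract_background(img: GrayscaleImage, constant: float = DEFAULT_BACKGROUND) -> GrayscaleImage:
    """Subtract a constant background level, clipping at zero.

    Clipping guarantees a zero background so that pixel positivity — the
    foreground criterion used by the lacunarity box masses — is well defined.
    """
    if constant < 0:
        raise ValueError("background constant must be nonnegative")
    return GrayscaleImage(np.clip(img.pixels - constant, 0.0, None), mask=img.mask)


def to_grayscale(rgb_image: np.ndarray, bit_depth: int = 8) -> GrayscaleImage:
    """Convert an (H, W, 3) colour image to luminance grayscale.

    Uses Rec. 601 weights (0.299 R + 0.587 G + 0.114 B), rounding to the
    integer grid of the source bit depth.
    """
    arr = np.asarray(rgb_image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a 3-channel (H, W, 3) image")
    gray = arr @ np.asarray(REC601_WEIGHTS)
    gray = np.clip(np.rint(gray), 0, 2**bit_depth - 1)
    return GrayscaleImage(gray)


def apply_roi(img: GrayscaleImage, mask: np.ndarray) -> GrayscaleImage:
    """Restrict an image to a region of interest.

    Pixels outside the mask are zeroed and the mask is attached, so box scans
    can drop boxes lying entirely outside the selected cell.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != img.shape:
        raise ValueError("mask shape must match image")
    if not m.any():
        raise ValueError("mask is empty")
    return GrayscaleImage(np.where(m, img.pixels, 0.0), mask=m)


def binarize(img: GrayscaleImage, rule: str = "positive", threshold: float | None = None) -> GrayscaleImage:
    """Threshold an image to a binary (0/1) foreground map.

    rule="positive" keeps strictly positive pixels (the natural criterion on
    a zero-background image); rule="fixed" keeps pixels >= `threshold`;
    rule="otsu" picks the two-class variance-maximising threshold.
    """
    px = img.pixels
    if rule == "positive":
        binary = px > 0
    elif rule == "fixed":
        if threshold is None or threshold < 0:
            raise ValueError("fixed rule needs a nonnegative threshold")
        binary = px >= threshold
    elif rule == "otsu":
        if np.ptp(px) == 0:
            raise ValueError("otsu undefined on a constant image")
        binary = px > threshold_otsu(px)
    else:
        raise ValueError(f"unknown binarization rule: {rule!r}")
    if not binary.any():
        raise ValueError("binarization produced an empty foreground")
    return GrayscaleImage(binary.astype(float), mask=img.mask)


def invert_intensity(img: GrayscaleImage, max_value: float | None = None) -> GrayscaleImage:
    """Invert intensities (dark-on-light -> light-on-dark) about `max_value`."""
    top = float(img.pixels.max()) if max_value is None else float(max_value)
    return GrayscaleImage(np.clip(top - img.pixels, 0.0, None), mask=img.mask)


# --- file I/O -------------------------------------------------------------

def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def read_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page TIFF (or PNG) as an image stack."""
    arr = np.asarray(_read_array(path), dtype=float)
    if arr.ndim == 2:
        pages = (arr,)
    elif arr.ndim == 3:
        pages = tuple(arr[i] for i in range(arr.shape[0]))
    else:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as a stack")
    depth = 16 if max(p.max(initial=0) for p in pages) > 255 else 8
    return ImageStack(pages, bit_depth=depth)


def read_image(path: str | Path) -> GrayscaleImage:
    """Read a 2-D grayscale image; RGB inputs are luminance-converted."""
    arr = np.asarray(_read_array(path), dtype=float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return to_grayscale(arr[..., :3])
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret shape {arr.shape} as a grayscale image")
    return GrayscaleImage(arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image; any nonzero pixel counts as true."""
    arr = np.asarray(_read_array(path))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def write_image(img: GrayscaleImage, path: str | Path, bit_depth: int = 16) -> None:
    """Write an image as single-page TIFF (16-bit by default) or PNG."""
    path = Path(path)
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    data = np.clip(np.rint(img.pixels), 0, 2**bit_depth - 1).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
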