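"""Image conditioning: 8-bit conversion, edge enhancement, binarization,
skeletonization.

This reproduces the conditioning chain applied to vascular plexus images
before quantification: convert to 8-bit, sharpen edges, reduce to a binary
(black/white) raster, and thin the vessel foreground to its unit-width
medial skeleton.  Foreground polarity follows the blood-vessel convention:
dark ("black") pixels are vessel/blood.

Edge enhancement is an unsharp mask (Gaussian blur of radius ``radius``,
gain ``amount``) followed by a linear contrast stretch; binarization defaults
to Otsu's threshold with dark foreground; thinning is the standard
two-subiteration morphological algorithm producing an 8-connected skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .raster_io import GrayImage, InputError


@dataclass
class BinaryMask:
    """Boolean raster; True = foreground (vessel/blood)."""

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("mask must be a non-empty 2-D boolean raster")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class SkeletonMask(BinaryMask):
    """Unit-width 8-connected medial-line mask with topology annotations."""

    branch_points: list[tuple[int, int]] = field(default_factory=list)
    end_points: list[tuple[int, int]] = field(default_factory=list)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_8bit(image: GrayImage) -> GrayImage:
    """Linearly stretch an image to 8-bit integers in [0, 255].

    The minimum maps to 0 and the maximum to 255 (round half up); a constant
    image maps to all zeros.  Already-full-range 8-bit images pass through
    unchanged.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = _round_half_up((px - lo) * (255.0 / (hi - lo)))
    return GrayImage(out.astype(np.uint8), pixel_size=image.pixel_size)


def enhance_edges(image: GrayImage, amount: float = 1.0, radius: float = 2.0) -> GrayImage:
    """Unsharp-mask edge enhancement with a final linear contrast stretch.

    ``out = img + amount * (img - gaussian(img, radius))`` clipped to
    [0, 255], then stretched to full range.  ``amount = 0`` returns the
    input unchanged; a constant image is returned unchanged at any amount.
    """
    if amount < 0:
        raise InputError(f"amount must be >= 0, got {amount}")
    if radius < 1:
        raise InputError(f"radius must be >= 1 pixel, got {radius}")
    if amount == 0:
        return GrayImage(image.pixels.copy(), pixel_size=image.pixel_size)
    px = image.pixels.astype(np.float64)
    blurred = ndimage.gaussian_filter(px, sigma=radius)
    sharp = np.clip(px + amount * (px - blurred), 0.0, 255.0)
    lo, hi = float(sharp.min()), float(sharp.max())
    if hi > lo:
        sharp = (sharp - lo) * (255.0 / (hi - lo))
    out = _round_half_up(sharp).astype(np.uint8)
    return GrayImage(out, pixel_size=image.pixel_size)


def binarize(
    image: GrayImage,
    method: str = "otsu",
    threshold: float | None = None,
    foreground: str = "dark",
) -> BinaryMask:
    """Threshold an image into a vessel mask.

    ``foreground="dark"`` (the default) marks pixels <= threshold as vessel,
    matching the dark-vessel/blood convention; ``"bright"`` is its logical
    complement.  ``method="otsu"`` picks the integer threshold maximizing
    between-class variance; ``method="fixed"`` uses ``threshold`` directly.
    """
    if foreground not in ("dark", "bright"):
        raise InputError(f"foreground must be 'dark' or 'bright', got {foreground!r}")
    px = image.pixels
    if method == "otsu":
        if float(px.min()) == float(px.max()):
            warnings.warn(
                "Otsu threshold undefined on a constant image; "
                "returning an empty-foreground mask",
                stacklevel=2,
            )
            return BinaryMask(np.zeros(px.shape, bool), pixel_size=image.pixel_size)
        thr = float(threshold_otsu(px))
    elif method == "fixed":
        if threshold is None or not (0 <= threshold <= 255):
            raise InputError(f"fixed method needs a threshold in [0, 255], got {threshold}")
        thr = float(threshold)
    else:
        raise InputError(f"unknown binarization method {method!r}")
    dark = px <= thr
    return BinaryMask(dark if foreground == "dark" else ~dark, pixel_size=image.pixel_size)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def skeletonize(mask: BinaryMask) -> SkeletonMask:
    """Thin a binary mask to its 8-connected unit-width medial skeleton.

    Uses two-subiteration morphological thinning, which preserves the
    8-connected component topology of the source mask.  Branch points
    (skeleton pixels with >= 3 skeleton neighbours) and end points (exactly
    1 neighbour) are annotated on the result.
    """
    skel = _sk_skeletonize(mask.pixels)
    nb = _neighbor_counts(skel)
    branch = np.argwhere(skel & (nb >= 3))
    ends = np.argwhere(skel & (nb == 1))
    return SkeletonMask(
        skel,
        pixel_size=mask.pixel_size,
        branch_points=[tuple(p) for p in branch],
        end_points=[tuple(p) for p in ends],
    )
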