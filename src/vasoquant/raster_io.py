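"""Raster I/O and region-of-interest handling for planar vascular images.

The pipeline consumes 2-D grayscale rasters of the early vitelline vascular
plexus of the chick extra-embryonic membrane (or any planar vessel network
imaged en face).  Every stage operates on a :class:`GrayImage`: a 2-D scalar
array plus optional physical pixel size in micrometres.

Coordinate conventions, used everywhere in the package:

* 0-based indices, row-major, origin at the top-left corner;
* extents are half-open: a region of ``n_rows`` starting at ``row0`` covers
  rows ``row0 .. row0 + n_rows - 1``.

RGB inputs are converted to luminance with fixed Rec. 709 weights
(0.2125, 0.7154, 0.0721); 16-bit inputs are linearly rescaled to the 8-bit
range at load time, since the whole analysis chain is defined on 8-bit data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: Rec. 709 luminance weights used for RGB -> gray conversion.
RGB_WEIGHTS = (0.2125, 0.7154, 0.0721)

#: Physical area (mm^2) and pixel grid of the standard analysis region:
#: the patch of the right-lateral vitelline plexus used for quantification.
ROI_AREA_MM2 = 177.0
ROI_SHAPE = (1100, 1800)


class InputError(ValueError):
    """Raised for unreadable, malformed, or out-of-contract inputs."""


@dataclass
class GrayImage:
    """2-D scalar raster with optional physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of intensities, either 8-bit integers in [0, 255] or
        normalized floats in [0, 1] (floats up to 255 are tolerated for
        intermediate results).
    pixel_size
        Physical edge length of one pixel in micrometres, if known.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise InputError("zero-sized image")
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise InputError(f"intensities outside [0, 255]: range [{lo}, {hi}]")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise InputError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangular region, 0-based, half-open extents."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise InputError(f"ROI corner must be non-negative: ({self.row0}, {self.col0})")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputError(f"ROI extents must be >= 1: ({self.n_rows}, {self.n_cols})")

    @property
    def row_end(self) -> int:
        return self.row0 + self.n_rows

    @property
    def col_end(self) -> int:
        return self.col0 + self.n_cols

    def area_px(self) -> int:
        return self.n_rows * self.n_cols


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse channels and rescale to 8-bit uint8."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise InputError(f"{path}: unsupported channel count {arr.shape[2]}")
        w = np.asarray(RGB_WEIGHTS, dtype=np.float64)
        arr = arr.astype(np.float64) @ w
    elif arr.ndim != 2:
        raise InputError(f"{path}: unsupported image dimensionality {arr.ndim}")

    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        scaled = arr.astype(np.float64) * (255.0 / 65535.0)
    elif np.issubdtype(arr.dtype, np.floating):
        hi = float(arr.max()) if arr.size else 0.0
        # Luminance of uint8 RGB or a [0,1]-normalized raster.
        scaled = arr if hi > 1.0 else arr * 255.0
    elif np.issubdtype(arr.dtype, np.integer):
        scaled = arr.astype(np.float64)
    else:
        raise InputError(f"{path}: unsupported dtype {arr.dtype}")
    return np.floor(np.clip(scaled, 0, 255) + 0.5).astype(np.uint8)


def load_image(path: str | Path, pixel_size: float | None = None) -> GrayImage:
    """Read a TIFF or PNG image as an 8-bit :class:`GrayImage`.

    RGB inputs are converted to luminance with :data:`RGB_WEIGHTS`; 16-bit
    inputs are linearly rescaled to [0, 255].
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise InputError(f"cannot read image: {path} (file not found)") from None
    except Exception as exc:  # noqa: BLE001 - present the failing path
        raise InputError(f"cannot read image: {path} ({exc})") from exc
    if arr.size == 0:
        raise InputError(f"{path}: zero-sized image")
    logger.info(
        "loaded %s: shape=%s dtype=%s channels=%d",
        path, arr.shape[:2], arr.dtype, arr.shape[2] if arr.ndim == 3 else 1,
    )
    return GrayImage(_to_gray(arr, path), pixel_size=pixel_size)


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale TIFF or PNG (chosen by file suffix)."""
    path = Path(path)
    px = image.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = np.floor(np.clip(px, 0, 255) + 0.5)
    iio.imwrite(path, px.astype(np.uint8))


def extract_roi(image: GrayImage, roi: RegionOfInterest) -> GrayImage:
    """Copy a rectangular region out of an image, preserving pixel size."""
    if roi.row_end > image.height or roi.col_end > image.width:
        raise InputError(
            f"ROI rows [{roi.row0}, {roi.row_end}) x cols [{roi.col0}, {roi.col_end}) "
            f"exceeds image bounds {image.height} x {image.width}"
        )
    sub = image.pixels[roi.row0:roi.row_end, roi.col0:roi.col_end].copy()
    return replace(image, pixels=sub)


def default_pixel_size(
    area_mm2: float = ROI_AREA_MM2,
    shape: tuple[int, int] = ROI_SHAPE,
) -> float:
    """Micrometres per pixel implied by a physical ROI area over a pixel grid.

    The default derives from the standard analysis region: ~177 mm^2 imaged
    onto 1100 x 1800 pixels, i.e. sqrt(177e6 um^2 / 1.98e6 px) ~= 9.45 um/px.
    """
    n_px = shape[0] * shape[1]
    if area_mm2 <= 0 or n_px <= 0:
        raise InputError("area and pixel counts must be positive")
    return math.sqrt(area_mm2 * 1e6 / n_px)
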