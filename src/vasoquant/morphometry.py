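"""Capillary-density morphometry: mean capillary area (MCA).

MCA is the mean percentage of foreground ("black" = blood) pixels over a
set of vessel-free patches of the binarized plexus.  It is an area-fraction
surrogate for capillary density: patches are chosen so that no branch
vessel crosses them, leaving only the fine capillary signal.

Patch selection is automated and deterministic: candidate positions are
scanned on a fixed stride in raster order and a patch is admitted when no
foreground connected component intersecting it is wider than
``max_vessel_width``.  Component width is the caliper width, measured as
2x the maximum of the Euclidean distance transform inside the component —
so the entire vessel tree (one wide connected component) is excluded even
where its terminal twigs are thin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import BinaryMask, SkeletonMask
from .raster_io import InputError, RegionOfInterest

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class Patch:
    """A measured patch: its region and its foreground percentage."""

    roi: RegionOfInterest
    foreground_percent: float


@dataclass
class MorphometryResult:
    """Per-patch foreground percentages and their mean (the MCA)."""

    patches: list[Patch]
    mca: float


def component_widths(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Label 8-connected foreground components and measure their widths.

    Returns ``(labels, widths)`` where ``labels`` is the label raster and
    ``widths[i]`` is the caliper width (2 x max EDT, pixels) of component
    label ``i + 1``.
    """
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return labels, np.empty(0)
    edt = ndimage.distance_transform_edt(mask.pixels)
    widths = 2.0 * ndimage.maximum(edt, labels, index=np.arange(1, n + 1))
    return labels, np.atleast_1d(widths)


def select_patches(
    mask: BinaryMask,
    skeleton: SkeletonMask | None = None,
    k: int = 5,
    patch_size: int = 64,
    stride: int | None = None,
    max_vessel_width: float = 4.0,
) -> list[RegionOfInterest]:
    """Deterministically pick the first k vessel-free patches in raster order.

    Candidate top-left corners lie on a ``stride`` grid (default
    ``patch_size``, making patches disjoint).  A patch is admissible when no
    foreground component intersecting it is wider than ``max_vessel_width``.
    The ``skeleton`` argument is accepted for interface symmetry with the
    quantification chain; admissibility is decided on the mask's components.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if max_vessel_width < 1:
        raise InputError(f"max_vessel_width must be >= 1 px, got {max_vessel_width}")
    if patch_size > min(mask.shape):
        raise InputError(
            f"patch_size {patch_size} exceeds mask extent {mask.shape}"
        )
    stride = stride or patch_size
    labels, widths = component_widths(mask)
    wide = np.zeros(len(widths) + 1, dtype=bool)  # index 0 = background
    if len(widths):
        wide[1:] = widths > max_vessel_width

    chosen: list[RegionOfInterest] = []
    for r0 in range(0, mask.height - patch_size + 1, stride):
        for c0 in range(0, mask.width - patch_size + 1, stride):
            window = labels[r0:r0 + patch_size, c0:c0 + patch_size]
            if wide[window].any():
                continue
            chosen.append(RegionOfInterest(r0, c0, patch_size, patch_size))
            if len(chosen) == k:
                return chosen
    raise InputError(
        f"only {len(chosen)} admissible patch(es) found, need {k}; "
        f"limiting parameters: patch_size={patch_size}, "
        f"max_vessel_width={max_vessel_width}"
    )


def mean_capillary_area(
    mask: BinaryMask,
    patches: list[RegionOfInterest],
) -> MorphometryResult:
    """Percentage of foreground pixels per patch and their mean (MCA)."""
    if not patches:
        raise InputError("empty patch list")
    measured = []
    for roi in patches:
        if roi.row_end > mask.height or roi.col_end > mask.width:
            raise InputError(f"patch {roi} exceeds mask bounds {mask.shape}")
        window = mask.pixels[roi.row0:roi.row_end, roi.col0:roi.col_end]
        pct = 100.0 * np.count_nonzero(window) / window.size
        measured.append(Patch(roi, pct))
    mca = float(np.mean([p.foreground_percent for p in measured]))
    return MorphometryResult(measured, mca)
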