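"""End-to-end quantification of one image or a cohort.

``quantify_image`` runs the full chain on a grayscale image and returns a
JSON-serializable report: the box-counting dimension of the skeletonized
vessel pattern (Df), the mean capillary area over vessel-free patches
(MCA), and the resolved parameter set (provenance).
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .fractal import box_counts, fit_df
from .morphometry import mean_capillary_area, select_patches
from .preprocess import binarize, enhance_edges, skeletonize, to_8bit
from .raster_io import GrayImage


def quantify_image(image: GrayImage, config: PipelineConfig | None = None) -> dict:
    """Quantify one plexus image: Df of the skeleton and MCA of the mask.

    The conditioning chain (8-bit, unsharp enhancement, binarization) runs
    once; Df is fitted on the skeletonized mask (or the raw mask when
    ``config.skeletonize`` is off) and MCA on vessel-free patches of the
    unskeletonized mask.
    """
    config = config or PipelineConfig()
    img = to_8bit(image)
    img = enhance_edges(img, config.enhance_amount, config.enhance_radius)
    mask = binarize(img, config.binarize_method, config.threshold, config.foreground)
    skeleton = skeletonize(mask)

    df_target = skeleton if config.skeletonize else mask
    curve = box_counts(df_target, config.box_sizes, config.average_offsets)
    est = fit_df(curve, config.fit_range)

    patches = select_patches(
        mask,
        skeleton,
        k=config.n_patches,
        patch_size=config.patch_size,
        stride=config.patch_stride,
        max_vessel_width=config.max_vessel_width,
    )
    morpho = mean_capillary_area(mask, patches)

    return {
        "df": est.df,
        "df_stderr": est.stderr,
        "df_r_squared": est.r_squared,
        "box_sizes": curve.sizes.tolist(),
        "box_counts": curve.counts.tolist(),
        "fit_sizes": np.asarray(est.fit_sizes).tolist(),
        "mca": morpho.mca,
        "patches": [
            {
                "row0": p.roi.row0, "col0": p.roi.col0,
                "n_rows": p.roi.n_rows, "n_cols": p.roi.n_cols,
                "foreground_percent": p.foreground_percent,
            }
            for p in morpho.patches
        ],
        "params": config.to_dict(),
    }
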