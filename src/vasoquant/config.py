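"""Run configuration shared by the pipeline stages and the CLI.

Every quantification run is driven by a :class:`PipelineConfig`.  The
resolved parameter set is serialized into each JSON report so that a report
is always self-describing (provenance).  Config files are flat TOML tables;
CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """Parameters of the quantification chain, with defaults.

    Preprocessing: unsharp-mask gain/radius, thresholding method and
    polarity.  Fractal: whether the box counts run on the skeleton (the
    production path) or the raw mask (the validation path for patterns of
    known dimension), the box-size schedule, and the fit range.
    Morphometry: patch geometry and the vessel-width exclusion criterion.
    """

    # preprocess
    enhance_amount: float = 1.0        # unsharp gain a; 0 disables enhancement
    enhance_radius: float = 2.0        # Gaussian radius r, pixels
    binarize_method: str = "otsu"      # "otsu" | "fixed"
    threshold: float | None = None     # used by "fixed"
    foreground: str = "dark"           # vessel polarity
    # fractal
    skeletonize: bool = True           # count boxes on the skeleton
    box_sizes: list[int] | None = None     # None -> powers of 2 up to min(H,W)/4
    fit_range: list[int] | None = None     # subset of sizes used in the fit
    average_offsets: bool = False      # average counts over shifted grids
    # morphometry
    n_patches: int = 5
    patch_size: int = 64
    patch_stride: int | None = None    # None -> patch_size (disjoint tiling)
    max_vessel_width: float = 4.0      # caliper width (px) above which a
                                       # component counts as a branch vessel
    # bookkeeping
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat TOML key-value file; unknown keys are rejected."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
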