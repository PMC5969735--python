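"""Synthetic inputs: deterministic fractals and stochastic vascular trees.

Two families of generated data feed the validation of the quantification
chain:

* **Deterministic fractals of known box dimension** (line, filled square,
  Sierpinski triangle, Sierpinski carpet) are the calibration standards for
  the Df estimator.  The self-similar patterns are rendered exactly, down to
  single-pixel scale, on rasters whose edge is a power of the generator's
  base; ``depth`` declares the coarsest guaranteed lattice (the raster edge
  must be base**m with m >= depth) and fixes the closed-form foreground
  count on that lattice (triangle: 3**depth boxes of edge size/2**depth).

* **Stochastic planar vascular trees** emulate en-face images of an early
  vitelline plexus: a trunk vessel entering from the image edge bifurcates
  recursively with tunable probability, angle, and length/width decay, and
  a random capillary speckle covers the avascular background.  A single
  ``drug_effect`` knob in [0, 1] jointly suppresses branching and capillary
  density (effective branch probability and speckle density are both scaled
  by ``1 - drug_effect``), reproducing the treated-vs-control contrast of an
  anti-angiogenic exposure: retarded branching plus capillary loss.

All randomness flows through ``numpy.random.default_rng`` (PCG64) with
explicit seeds; identical parameters and seed give bit-identical output.
Per-image seeds in a cohort derive from ``SeedSequence(master_seed,
spawn_key=(arm_index, image_index))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import BinaryMask
from .raster_io import GrayImage, InputError, save_image

#: Analytic box dimension of each deterministic pattern.
ANALYTIC_DIMENSION = {
    "line": 1.0,
    "filled_square": 2.0,
    "sierpinski_triangle": math.log(3) / math.log(2),
    "sierpinski_carpet": math.log(8) / math.log(3),
}

_FRACTAL_BASE = {"sierpinski_triangle": 2, "sierpinski_carpet": 3}

#: Gray levels of the rendered scene (8-bit, dark vessels on bright field).
BACKGROUND_LEVEL = 245
VESSEL_LEVEL = 40
CAPILLARY_LEVEL = 90


@dataclass(frozen=True)
class FractalSpec:
    """Deterministic test pattern of analytically known box dimension."""

    kind: str
    depth: int = 1
    size: int = 64

    @property
    def dimension(self) -> float:
        return ANALYTIC_DIMENSION[self.kind]


def generate_fractal(spec: FractalSpec) -> BinaryMask:
    """Render a deterministic pattern on a ``size`` x ``size`` raster.

    ``sierpinski_triangle`` requires size = 2**m, ``sierpinski_carpet``
    size = 3**m, with m >= depth; both are rendered self-similarly down to
    single pixels, so on the depth lattice the occupied-box counts equal the
    closed forms 3**depth and 8**depth.
    """
    if spec.kind not in ANALYTIC_DIMENSION:
        raise InputError(f"unknown fractal kind {spec.kind!r}")
    if spec.size < 1 or spec.depth < 0:
        raise InputError(f"size and depth must be positive, got {spec}")
    size = spec.size
    if spec.kind in _FRACTAL_BASE:
        base = _FRACTAL_BASE[spec.kind]
        m = round(math.log(size, base))
        if base**m != size or m < spec.depth:
            raise InputError(
                f"{spec.kind} needs size = {base}**m with m >= depth={spec.depth}, "
                f"got size={size}"
            )
    mask = np.zeros((size, size), dtype=bool)
    if spec.kind == "line":
        mask[size // 2, :] = True
    elif spec.kind == "filled_square":
        mask[:, :] = True
    elif spec.kind == "sierpinski_triangle":
        idx = np.arange(size)
        mask = np.bitwise_and.outer(idx, idx) == 0
    else:  # sierpinski_carpet: drop cells whose base-3 digits are both 1
        idx = np.arange(size)
        n_digits = round(math.log(size, 3))
        bad = np.zeros((size, size), dtype=bool)
        for p in range(n_digits):
            d = (idx // 3**p) % 3 == 1
            bad |= np.logical_and.outer(d, d)
        mask = ~bad
    return BinaryMask(mask)


@dataclass(frozen=True)
class VascularTreeParams:
    """Parameters of the stochastic planar vascular tree.

    The trunk enters at the left edge mid-height and grows rightward;
    at each generation every active tip bifurcates with probability
    ``branch_probability * (1 - drug_effect)`` into two children deflected
    by ``±(branch_angle_mean + N(0, angle_jitter_sd))`` degrees, with
    segment length and stroke width shrunk by ``length_decay`` and
    ``width_decay``.  ``capillary_density * (1 - drug_effect)`` is the
    coverage fraction of the background speckle standing in for the
    capillary bed.
    """

    trunk_width: float = 8.0          # px
    trunk_length: float = 140.0       # px
    branch_probability: float = 0.9   # per tip per generation
    branch_angle_mean: float = 35.0   # degrees
    angle_jitter_sd: float = 8.0      # degrees
    length_decay: float = 0.78
    width_decay: float = 0.8
    generations: int = 7
    capillary_density: float = 0.14   # background speckle coverage in [0, 1]
    drug_effect: float = 0.0          # joint suppression knob in [0, 1]
    seed: int = 0
    shape: tuple[int, int] = (550, 900)   # rows x cols of the canvas

    def __post_init__(self) -> None:
        for name in ("branch_probability", "capillary_density", "drug_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        for name in ("length_decay", "width_decay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if self.trunk_width < 1 or self.trunk_length < 1 or self.generations < 0:
            raise InputError("trunk geometry and generations must be positive")

    @property
    def effective_branch_probability(self) -> float:
        return self.branch_probability * (1.0 - self.drug_effect)

    @property
    def effective_capillary_density(self) -> float:
        return self.capillary_density * (1.0 - self.drug_effect)


@dataclass(frozen=True)
class Segment:
    """One vessel stroke: endpoints (row, col) and width in pixels."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float
    generation: int


@dataclass
class SimulationResult:
    """Rendered scene plus exact ground truth."""

    image: GrayImage                  # anti-aliased grayscale rendering
    vessel_mask: BinaryMask           # exact vessel ground truth
    capillary_mask: BinaryMask        # exact speckle ground truth
    segments: list[Segment] = field(default_factory=list)
    n_terminal_tips: int = 0

    @property
    def mask(self) -> BinaryMask:
        """Combined foreground ground truth (vessels + capillaries)."""
        return BinaryMask(
            self.vessel_mask.pixels | self.capillary_mask.pixels,
            pixel_size=self.vessel_mask.pixel_size,
        )


def _grow_tree(params: VascularTreeParams, rng: np.random.Generator) -> tuple[list[Segment], int]:
    """Recursive tip bifurcation; returns segments and terminal-tip count."""
    rows, cols = params.shape
    p_branch = params.effective_branch_probability
    segments: list[Segment] = []
    # tips: (position, heading degrees, generation of the NEXT segment)
    start = (rows / 2.0, 2.0)
    trunk_end = (rows / 2.0, 2.0 + params.trunk_length)
    segments.append(Segment(start, trunk_end, params.trunk_width, 0))
    tips = [(trunk_end, 0.0)]
    n_terminal = 0
    for gen in range(1, params.generations + 1):
        length = params.trunk_length * params.length_decay**gen
        width = max(params.trunk_width * params.width_decay**gen, 1.0)
        next_tips = []
        for pos, heading in tips:
            if rng.random() < p_branch:
                for sign in (+1.0, -1.0):
                    jitter = rng.normal(0.0, params.angle_jitter_sd) if params.angle_jitter_sd > 0 else 0.0
                    ang = heading + sign * params.branch_angle_mean + jitter
                    rad = math.radians(ang)
                    end = (pos[0] + length * math.sin(rad), pos[1] + length * math.cos(rad))
                    segments.append(Segment(pos, end, width, gen))
                    next_tips.append((end, ang))
            else:
                n_terminal += 1
        tips = next_tips
    n_terminal += len(tips)
    return segments, n_terminal


def _stamp_segments(
    segments: list[Segment],
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize strokes; returns (exact mask, anti-alias coverage in [0,1])."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    coverage = np.zeros(shape, dtype=np.float64)
    for seg in segments:
        half = seg.width / 2.0
        r0, c0 = seg.p0
        r1, c1 = seg.p1
        pad = half + 1.5
        rlo = max(int(math.floor(min(r0, r1) - pad)), 0)
        rhi = min(int(math.ceil(max(r0, r1) + pad)) + 1, rows)
        clo = max(int(math.floor(min(c0, c1) - pad)), 0)
        chi = min(int(math.ceil(max(c0, c1) + pad)) + 1, cols)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        # distance from pixel centres to the segment
        dr, dc = r1 - r0, c1 - c0
        seg_len2 = dr * dr + dc * dc
        if seg_len2 == 0:
            dist = np.hypot(rr - r0, cc - c0)
        else:
            t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / seg_len2, 0.0, 1.0)
            dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
        mask[rlo:rhi, clo:chi] |= dist <= half
        cov = np.clip(half + 0.5 - dist, 0.0, 1.0)
        np.maximum(coverage[rlo:rhi, clo:chi], cov, out=coverage[rlo:rhi, clo:chi])
    return mask, coverage


def simulate_vascular_tree(params: VascularTreeParams) -> SimulationResult:
    """Render one synthetic plexus scene with exact ground truth.

    Vessels are drawn as dark anti-aliased strokes on a bright field; the
    capillary speckle is seeded uniform random foreground at the effective
    density, placed only beyond a guard band of two trunk widths around the
    vessels so that vessel-free patches stay verifiably vessel-free.
    """
    rng = np.random.default_rng(params.seed)
    segments, n_tips = _grow_tree(params, rng)
    vessel_mask, coverage = _stamp_segments(segments, params.shape)

    # capillary speckle outside the guard band
    guard = 2.0 * params.trunk_width
    dist_to_vessel = ndimage.distance_transform_edt(~vessel_mask)
    allowed = dist_to_vessel > guard
    speckle = (rng.random(params.shape) < params.effective_capillary_density) & allowed

    img = np.full(params.shape, float(BACKGROUND_LEVEL))
    img = img * (1.0 - coverage) + VESSEL_LEVEL * coverage
    img[speckle] = CAPILLARY_LEVEL
    img = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)

    return SimulationResult(
        image=GrayImage(img),
        vessel_mask=BinaryMask(vessel_mask),
        capillary_mask=BinaryMask(speckle),
        segments=segments,
        n_terminal_tips=n_tips,
    )


def derive_seed(master_seed: int, arm_index: int, image_index: int) -> int:
    """Per-image seed: SeedSequence(master, spawn_key=(arm, index)), < 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(arm_index, image_index))
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def cohort_params(
    n_per_arm: int,
    arms: list[float],
    base_params: VascularTreeParams | None = None,
    seed: int = 0,
) -> list[tuple[int, float, int, VascularTreeParams]]:
    """Parameter list for a multi-arm cohort: (arm_idx, drug_effect, img_idx, params)."""
    if n_per_arm < 1:
        raise InputError(f"n_per_arm must be >= 1, got {n_per_arm}")
    base = base_params or VascularTreeParams()
    out = []
    for a, effect in enumerate(arms):
        for i in range(n_per_arm):
            p = replace(base, drug_effect=effect, seed=derive_seed(seed, a, i))
            out.append((a, effect, i, p))
    return out


def generate_cohort(
    n_per_arm: int,
    arms: list[float],
    out_dir: str | Path,
    base_params: VascularTreeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a simulated cohort to disk: PNG per embryo + ``manifest.csv``.

    The manifest has one row per image with columns ``image`` (file name),
    ``arm`` (0-based arm index), ``drug_effect`` and ``seed``; identical
    master seeds reproduce byte-identical images and manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a, effect, i, p in cohort_params(n_per_arm, arms, base_params, seed):
        name = f"arm{a}_img{i:02d}.png"
        result = simulate_vascular_tree(p)
        save_image(result.image, out_dir / name)
        rows.append({"image": name, "arm": a, "drug_effect": effect, "seed": p.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
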