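# Methods

## Scope and model

The package quantifies planar (quasi-2-D) vascular networks imaged en face,
such as the early vitelline plexus of the chick extra-embryonic membrane.
Two endpoints are computed per image and compared across treatment arms:

* **Df**, the box-counting fractal dimension of the skeletonized vessel
  pattern — a measure of how densely the branching pattern fills the plane;
* **MCA**, the mean capillary area — the mean foreground percentage over
  vessel-free patches of the binarized image, an area-fraction surrogate
  for capillary density.

Both rest on the assumption that the plexus is effectively planar with
little vessel crossing, so that a 2-D binary projection is a faithful
representation of the network.

## Image conditioning

Images load as 8-bit grayscale; RGB collapses to luminance with fixed
Rec. 709 weights (0.2125, 0.7154, 0.0721) and 16-bit data rescale linearly
to [0, 255], since the analysis chain is defined on 8-bit rasters.
Coordinates are 0-based, row-major, origin top-left, half-open extents —
stated here once and used everywhere.  The default physical scale,
`default_pixel_size()` ≈ 9.45 µm/px, derives from the standard analysis
region of ~177 mm² imaged onto 1100 × 1800 pixels; it is metadata only and
enters no computation.

The conditioning chain is: linear stretch to 8-bit (round half up;
constant images map to 0) → unsharp-mask edge enhancement
(`out = img + a·(img − gaussian(img, r))`, clipped then stretched; defaults
a = 1.0, r = 2 px; a = 0 disables the stage) → binarization (default Otsu
threshold, dark foreground = vessel/blood; a fixed threshold is available
for exact reproducibility) → two-subiteration morphological thinning to a
unit-width 8-connected skeleton, which preserves component topology.  The
source toolchains for this kind of analysis are interactive and do not
document their exact operations, so the chain here is a documented,
parameter-exposed stand-in rather than a reconstruction; every run logs the
resolved parameter set into its JSON report.

Note that parallel-thinning implementations differ legitimately in corner
retention; downstream quantities (component counts, medial lengths, box
counts) are insensitive to these single-pixel differences.

## Box counting and the Df fit

For each box edge *s* the raster is tiled by a single origin-anchored grid
(partial boxes at the far edges count) and *N(s)* = occupied boxes.  The
default schedule is powers of 2 from 1 up to the largest power ≤ min(H,W)/4.
Df = −slope of the OLS fit of ln *N(s)* on ln *s*; the fit reports its
standard error and r².  Saturated scales (N = 1 beyond the first) are
trimmed because they only flatten the regression.  Fewer than three usable
scales is an error, not a guess.

A single anchored grid is placement-sensitive: patterns not aligned to the
dyadic lattice count systematically low at coarse scales (observed ~0.05–0.08
shifts of Df for a depth-6 Sierpinski triangle embedded off-lattice).  The
`average_offsets` flag averages counts over nine grid anchors (row/column
offsets 0, s/3, 2s/3), which reduces the shift sensitivity to < 0.05.  The
default stays single-grid, matching the common box-counting convention of
the field's interactive tools.

Df is computed on the skeleton in the production path (the branching
pattern, not vessel calibre, is the object of interest).  A config switch
(`skeletonize = false`, or passing a `BinaryMask` directly) bypasses
preprocessing for validation against deterministic patterns: the estimator
recovers 1.0 (line), 2.0 (filled square), log3/log2 ≈ 1.585 (Sierpinski
triangle, exactly, since the pattern is dyadic), and log8/log3 ≈ 1.893
(Sierpinski carpet; the dyadic schedule on a base-3 pattern gives 1.849, a
known scale-mismatch bias that stays within the ±0.05 validation band).

The deterministic generators render each pattern self-similar down to
single-pixel scale (triangle: pixel (i, j) set iff `i & j == 0`; carpet:
set unless some base-3 digit position has digit 1 in both coordinates).
`depth` declares the coarsest guaranteed lattice — the raster edge must be
base^m with m ≥ depth — and fixes the closed-form count on that lattice
(3^depth, 8^depth).  A depth-truncated rendering with solid blocks would
have local dimension 2 below the block scale and bias the fitted slope
upward; rendering to pixel scale keeps the box-count curve an exact power
law at every scale the schedule visits.

## Morphometry (MCA)

Patch selection is automated and deterministic to avoid the subjectivity of
manual area picking: candidate top-left corners scan a fixed stride grid in
raster order (default stride = patch size, 64 px, giving disjoint patches),
and the first k = 5 admissible patches are taken.  A patch is admissible
when no foreground connected component intersecting it counts as a branch
vessel, operationalized as caliper width — 2× the maximum of the Euclidean
distance transform inside the component — exceeding `max_vessel_width`
(default 4 px).  The width test applies to whole components of the full
mask, so a patch touching the vessel tree anywhere is rejected even where a
terminal twig is locally thin.  Manually supplied patch coordinates remain
possible through the library API.  MCA is the arithmetic mean of the patch
foreground percentages; too few admissible patches is a reported error, and
the limiting parameters are named in the message.

## Synthetic vasculature

The simulator is a statistical stand-in for assay images, not a biological
model (no hemodynamics, no growth-factor fields, no 3-D geometry).  A trunk
vessel enters at the left edge and grows rightward; at each of
`generations` rounds every active tip bifurcates with probability
`branch_probability` into two children deflected by ±(35° + N(0, 8°)), with
segment length and stroke width decaying by 0.78 and 0.8 per generation.
Strokes render anti-aliased (dark on a bright field) while the returned
ground-truth masks are exact, so estimator error is attributable to the
estimator rather than rasterization.  Capillaries are uniform random
foreground speckle at density `capillary_density` placed outside a guard
band of two trunk widths around the vessels, which keeps vessel-free
patches verifiably vessel-free.

`drug_effect` ∈ [0, 1] jointly scales the effective branch probability and
speckle density by (1 − drug_effect), emulating an exposure that both
retards branching and depletes the capillary bed.  Defaults: canvas
550 × 900 px (half the linear scale of the standard 1100 × 1800 analysis
region — the package's choice of working resolution; all effects are
scale-free percentages and slopes), trunk width 8 px and length 140 px,
branch probability 0.9, 7 generations, capillary density 0.14 — chosen so
an untreated scene yields MCA ≈ 14%, the magnitude reported for control
membranes in this assay class.  Three arms at drug effects (0, 0.4, 0.8)
with n = 10 per arm emulate a control/low-dose/high-dose design.

Determinism contract: PCG64 (`numpy.random.default_rng`) with explicit
seeds; identical parameters + seed give bit-identical images and masks.
Cohort per-image seeds derive from
`SeedSequence(master_seed, spawn_key=(arm_index, image_index))`, reduced
below 2³¹.

What the simulator does **not** emulate: uneven illumination, yolk texture
and autofluorescence, vessel crossings and anastomoses (the generated tree
is loop-free), haemorrhage blotches, and optical blur beyond stroke
anti-aliasing.  Passing validation on synthetic scenes therefore
demonstrates the estimators' correctness and dose-response sensitivity
under clean conditions, not robustness to real-microscopy artefacts — for
real images the binarization step is the fragile stage and may need a fixed
threshold chosen per batch.

## Group statistics

Per-arm summaries report mean, SEM = sd/√n (ddof = 1), and the Student-t
interval mean ∓ t_{1−α/2, n−1}·SEM (default 95%).  Display rounding is
half-up to 2 decimals; all computation keeps full precision.  Arms are
compared by classical one-way ANOVA with Tukey HSD post hoc on the
studentized-range distribution; an all-constant table returns F = 0, p = 1
by convention rather than NaN.

Relative expression uses the comparative-Ct method with amplification
efficiency fixed at 2 (no efficiency calibration is modelled): per sample
ΔCt = Ct_target − mean(reference Cts); per group, fold change =
2^−(mean ΔCt_group − mean ΔCt_control); the control group's fold change is
1 exactly.  Averaging the Cts of several reference genes (default B2M +
GAPDH, configurable to either alone) equals the geometric mean of their
relative quantities at efficiency 2.  Duplicate wells of a sample/gene pair
average before ΔCt.  Fold changes are invariant under adding a constant to
every Ct.

A caveat on published summary tables in this assay literature: intervals
printed as mean ± SEM (95% CI lo–hi) are only self-consistent when
lo = mean − t·SEM holds at the printed precision; where a printed bound is
inconsistent with the printed mean and SEM (rounding of the mean is the
usual cause), only the self-consistent bounds can serve as worked-example
oracles.

## Problem sizes and numerical choices

Validation patterns: 512²–1024² rasters (dimension recovery needs scales
spanning ≥ 2.5 decades).  Simulated cohorts: 550 × 900 px, 10–20 seeds per
arm.  Degenerate inputs have defined behaviour throughout: constant image →
Otsu warns and returns an empty mask; empty mask → box counting refuses
with a polarity hint; empty skeleton stays empty; n < 2 → no CI; a patch
request that cannot be met reports how many patches were found and which
parameter limited them.
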