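# Methods

## Scope and model of the data

`gliamorph` quantifies microglial morphology in 2D fluorescence
micrographs (Iba-1 staining, bright cells on dark background) and compares
morphology distributions across experimental arms — in the motivating use
case, healthy control, oxygen–glucose-deprived (OGD) injury, and
OGD + brain-derived extracellular-vesicle (BEV) treatment, each observed
at 0, 4, 24 and 48 h of exposure. The analysis unit is the individual
segmented cell; condition-level claims are made on distributions of cell
features (medians, shape-mode frequencies), never on single cells.

## Segmentation

Bright-object segmentation proceeds as: threshold → binarize
(`image >= t`) → remove objects *strictly* smaller than
`min_object_area_px` → fill interior holes → label with 8-connectivity
(thin diagonal processes must stay attached to their soma).

Seven histogram thresholds are available and surveyed side by side
(isodata, li, mean, minimum, otsu, triangle, yen; scikit-image
implementations). The default working threshold is Li's
minimum-cross-entropy method, which on bright-sparse fluorescence fields
sits low enough to keep thin processes. Two conventions are fixed here
because they change borderline results:

- **Cut-point convention.** The underlying criteria define foreground as
  `image > t`. This package binarizes as `image >= t`; when an optimizer
  lands exactly on an occupied gray level of an integer image the reported
  cut is nudged up half a gray step so the partition is preserved. For
  non-integer thresholds the two rules agree pixel for pixel.
- **Minimum-method robustness.** The minimum method (smooth the histogram
  with a 3-bin mean filter until two local maxima remain; threshold at the
  valley) misses a mode sitting at the extreme occupied gray level,
  because its maxima walk needs a descent after the peak. When that
  happens the same procedure is rerun with two empty guard bins appended
  on each side, which makes terminal modes detectable without changing the
  criterion.

The small-object cutoff defaults to 71 px², the value applied by the
workflow this package operationalizes. A helper derives a cutoff from
physical quantities as `fraction × avg_cell_area_um2 / pixel_size_um²`;
with the conventional average microglial area of 1600 μm², a 3.4527 μm/px
scale and the half-size rule this yields 67.11 px². The two constants
deliberately coexist: the derivation documents the reasoning, the config
value is what runs, and users with calibrated pixel sizes should derive
their own. "Smaller than" is strict — an object of exactly the cutoff
area survives.

## Per-cell features

Area, perimeter, axis lengths of the moment-equivalent ellipse, aspect
ratio (major/minor, ≥ 1 by construction) and circularity `4πA/P²` are
measured per labeled object. Degenerate objects (< 3 px, or zero minor
axis) are flagged and excluded from shape analysis but retained for QC
counting.

**Perimeter estimator.** Circularity is quadratically sensitive to the
perimeter estimate, and the common unit/√2 boundary-step estimator
overestimates a rasterized disk's circumference by ~6% — enough to push a
perfect disk's circularity to 0.89. This package instead traces the
8-connected boundary chain code (Moore neighborhood, with a
state-repetition stop so one-pixel-wide spurs close correctly) and applies
the Vossepoel–Smeulders corner-corrected weights,
`0.980·n_orth + 1.406·n_diag − 0.091·n_corner`, plus a π offset for the
half-pixel band between pixel centers and the true boundary (a Minkowski
offset of 0.5 px adds 2π·0.5 to any convex outline). Measured accuracy:
disk r = 50 px: +0.33%; axis-aligned square side 100: −2.3%; ellipse
60×30: −0.9%. Pixelated small compact objects can slightly exceed
circularity 1; values are left as measured. The estimator name is written
into output metadata since circularity values are only comparable under a
fixed estimator.

**Quadrants and edge removal.** Each mask is split into four equal tiles
(ceil/floor for odd sizes), objects are re-labeled per tile, and any
object touching a tile edge is removed — including the artificial edges
created by the split, so an object straddling the midline is dropped from
both neighboring tiles. This trades a known loss of cells for freedom
from partial-cell bias; the alternative (removing only at the original
image border) would keep split cell fragments whose geometry is
meaningless.

## Shape modes

Population shape analysis follows the contour-PCA + k-means family of
methods:

1. **Contour extraction** at the 0.5 iso-level (subpixel marching
   squares), longest loop, holes ignored (objects are hole-filled
   upstream). One pass of closed 3-point moving-average smoothing removes
   the staircase bias of the marching-squares polygon (raw polygon length
   overestimates a smooth boundary by ~6%, smoothed ~2%).
2. **Resampling** to `n_points = 50` points. Equal-arc interpolation along
   the input polygon does not make the output chords equal, so the
   redistribution is iterated to a fixed point (spacing CV < 1e-8); this
   also makes resampling idempotent and rotation-consistent.
3. **Registration**: centroid to origin, unit RMS radius, major principal
   axis of the point set rotated to horizontal (180° ambiguity resolved by
   the sign of the x third moment, falling back to the y third moment),
   counterclockwise orientation, start point at maximal x.
4. **Procrustes refinement**: principal-axis registration is degenerate
   for shapes with near-rotational symmetry (a 4-armed cell has an
   isotropic second moment, so its "major axis" is noise). Registered
   vectors are therefore aligned — best cyclic shift plus rotation, solved
   in closed form on the complex plane — to a reference iterated from the
   mean of the training shapes (3 rounds). The final reference is stored
   in the model so new cells are aligned identically at application time.
   Mirror images are *not* identified; reflection-sensitive users can
   augment their data.
5. **PCA** on the aligned training vectors. The retained dimension is the
   smallest explaining ≥ 90% of variance, capped at 20 (configurable);
   with full rank the basis reconstructs training vectors to numerical
   precision, which the test suite asserts.
6. **k-means** (k = 5 default, k-means++, 10 restarts, seeded) on training
   scores; all cells, train and test, are assigned to the nearest
   centroid, ties to the lower index. The train:test split is 80:20 at
   the cell level, stratified by image.
7. **Mode numbering** is by decreasing median member area, making SM
   labels stable across runs; a Ward dendrogram over the centroids gives
   the mode ordering used in figures.

The fitted model (mean shape, basis, centroids, linkage, alignment
reference) serializes to a single JSON file — the arrays are small
(≤ 20 × 100), so no binary sidecar is used and models are diffable and
portable.

## Population statistics

- **Shape-mode frequency tables**: percent of cells per mode for each
  (group, exposure) condition; rows carry their cell count and sum to 100.
  Conditions with no cells are reported missing, never zero-filled.
- **Fold change** of each feature versus the control group at matched
  exposure time, using medians (the per-cell feature distributions are
  heavy-tailed; median-with-IQR is the display convention this mirrors).
  Mean aggregation is available by config.
- **Kruskal–Wallis** (tie-corrected, χ² approximation) across groups,
  cells pooled within condition. When every observation is identical the
  statistic is reported as 0 with p = 1 (the tie correction would
  otherwise divide by zero). Cell-level pooling matches the scatter-plot
  convention of the field but is pseudoreplication-prone; per-image
  aggregation is the conservative alternative and is left to the user's
  design table.
- **Dunn's post hoc** z-tests on pooled ranks with tie correction,
  Bonferroni-adjusted by default (Holm and unadjusted available).
  Implemented in-package; the test suite pins it to hand-computed
  fixtures. α = 0.05 throughout.

## Assay formulas

Four pure scalar computations accompany the imaging pipeline:
cytotoxicity % = 100·PI⁺/total; EV purity = NTA particles per μg BCA
protein; dot-blot signal-density ratio = 100·vesicle/tissue density; and
qPCR fold change. The qPCR chain is: optional centering of every Cq by the
all-sample median (a plate-level normalization; it cancels in ΔΔCq when
applied uniformly, so it is exposed as a toggle), ΔCq against the
housekeeping gene per sample, ΔΔCq against the control group's median ΔCq
per gene, fold change 2^(−ΔΔCq). Group summaries are computed on the ΔΔCq
scale and then transformed, which keeps the control group's own median
fold change at exactly 1; 95% CIs come from a seeded bootstrap (10,000
resamples) of the median.

## Synthetic data generator

The generator renders what the downstream stages need to be tested
against, not photorealistic microscopy. Cells are drawn per class from
parameter ranges — soma radius, elongation, branch count/length/width,
branch-angle jitter — as an elliptical soma plus straight thick rays whose
angles are evenly spaced with bounded jitter (guaranteeing the requested
number of distinct processes). The default class library encodes the
canonical phenotypes: amoeboid (swollen disk, 11–16 px soma), transitional
(1–2 short branches), ramified (small 4.5–6.5 px soma, 3–6 long thin
processes), elongated and rod. Rendering is binary shape → 1 px Gaussian
edge blur → additive Gaussian noise (optional Poisson), enough texture to
exercise every histogram threshold while keeping the true label mask
exact. Placement is rejection sampling with 100 retries per cell and a
configurable separation margin, so ground truth and rendered mask
correspond one-to-one.

The default condition series mirrors a 3-arm × 4-time design: the healthy
arm stays ramification-dominant, the injured arm becomes
amoeboid-dominant, and the treated arm tracks the injured arm through 24 h
and then shifts toward ramified/elongated/rod mixtures at 48 h — the
qualitative trajectory reported for vesicle-treated injured tissue
(decreased median area and circularity, increased aspect ratio, shape-mode
mass moving from the round mode to branched modes). Per-image seeds are
derived by stable hashing of (group, time, replicate), so series are
reproducible image by image.

What the generator does **not** emulate: out-of-focus light and PSF
structure, intensity inhomogeneity across the field, touching/overlapping
cells, multi-channel co-stains, and 3D structure. Consequently, passing
tests demonstrate correctness of the measurement and clustering machinery
under known truth — not segmentation robustness on real confocal data,
where touching cells and uneven illumination are the dominant failure
modes.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest scale: 512²
synthetic fields with 25 cells, 3 images per condition for end-to-end
checks; 1000-cell populations for class-recovery checks; 10,000 null
simulations for type-I calibration. These sizes give stable directional
and calibration results while keeping a full run in tens of seconds.
Determinism is enforced end to end: a single global seed fans out to
per-stage child seeds by stable hashing of stage names, k-means and
bootstraps are seeded, and rerunning a pipeline config reproduces
artifact content hashes exactly.

## Known limitations

- No watershed or learned splitting of touching cells; overlapping cells
  merge into one object (the generator avoids overlap by construction).
- Circularity depends on the perimeter estimator; values are not
  comparable across packages using different estimators.
- Shape modes from k-means are a quantization of a continuum, not
  biological types; k = 5 is a display-resolution choice, and near-balanced
  clusterings can reshuffle under reseeding when classes genuinely overlap.
- Reflection-asymmetric phenotypes map to distinct modes (mirror images
  are not identified).
- Cell-level pooling in the statistics overstates effective sample size
  when images, not cells, are the independent unit.
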