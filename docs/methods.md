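# Methods

## Image model and corrections

A cyclic acquisition is modelled as, per cycle *c* with planted signal *s_c*
(expression rendered over cell masks plus a uniform autofluorescence
background, scaled by a per-image staining gain),

    tag_c        = F · g · (s_c + ρ · s_{c−1}) + dark
    postbleach_c = F · g · (ρ · s_c)           + dark

where *F* is the illumination field captured by the brightfield calibration
image (brightfield = B·F + dark), *g* = 1 − α·(r/r_max)² is a radial
vignette (mean-normalized; r_max the center-to-corner distance), and
ρ ∈ [0, 1) the fraction of a cycle's signal surviving its photobleach.
Poisson shot noise and Gaussian read noise are applied last when enabled.

Two deliberate modelling choices:

* **The vignette is not in the brightfield.**  If the calibration images
  carried *g*, flat-fielding would already remove the vignette and the
  vignetting-correction stage would be vacuous.  Keeping two separate
  multiplicative fields lets each correction be validated against its own
  planted artifact.  Physically this reads *F* as the lamp/illumination
  pattern and *g* as a fluorescence-path falloff.
* **A uniform autofluorescence background** (default 20 intensity units) is
  part of the signal.  Retrospective gain estimation needs support away from
  cells — the per-pixel median over the stack is dominated by this
  background — and it is also the autofluorescence that background
  normalization later addresses.

The corrections are exact inverses of this model in the noiseless limit:
flat-field removes *F* and dark (preserving scale via the mean-illumination
factor), subtracting the previous post-bleach image removes the ρ-term
pixelwise, and dividing by *g* removes the vignette.  With the true gain
supplied, the planted signal is recovered to machine precision (the test
bound is 1e−6 relative).  The estimated gain (median across ≥8 tag images,
Gaussian smoothing at `smoothing_scale` px, mean-normalized, floored at
1e−6 of its maximum) is a deliberately simple stand-in for regularized
energy-minimization shading estimators; on the synthetic fixtures it
correlates with the planted vignette at r ≈ 0.99.  A precomputed gain map
(e.g. estimated jointly across many samples, or by an external tool) can be
passed instead; per-stack vs joint estimation is the caller's choice.

Registration estimates one integer translation per cycle by phase
correlation of phase-contrast images against a reference cycle (subpixel
refinement behind `upsample_factor`); the same shift is applied to the
cycle's three images, exposed pixels are zero-filled, and shifts beyond
`max_shift` either abort or drop the cycle.

## Segmentation and reconciliation

The baseline segmenters are classical: Gaussian smoothing, Otsu threshold,
small-object removal, distance-transform markers (`peak_local_max` at a
minimum separation), watershed split.  For phase contrast, a local-variance
map (window 3 px) stands in for intensity, and the thresholded mask is
eroded by 2 px before splitting because the variance window dilates object
outlines and can bridge near-touching cells.  These parameters were set on
the synthetic fixtures (cells of nucleus radius ~5–9 px plus a 2–4 px
cytoplasm ring); they are exposed per call.  Externally produced label
masks (16-bit TIFF) substitute for either baseline — the rest of the
pipeline only consumes the mask contract.

"Reproduced in the nucleus mask" is operationalized as: a cell object is
kept iff some nucleus object has **strictly more than 50%** of its pixels
inside it; each nucleus goes to its majority cell, each kept cell is paired
with its largest-overlap qualifying nucleus, and the nucleus compartment is
clipped to the cell.  The criterion value is a documented choice (the
containment rule itself is the contract, its threshold was not prescribed).
Cells touching the image border are kept but flagged.  Exclusion polygons
remove cells whose centroid lies in their strict interior (a centroid
exactly on an edge survives).

## Features

Per cell: 6 morphology + 9 intensity features per marker (3 statistics × 3
compartments), with fixed column order (morphology block; then per marker
ME/TO/M20 × nucleus/cell/cytoplasm-membrane).  Conventions chosen for exact
testability against a per-pixel oracle:

* perimeter = count of unit pixel edges on the object/background interface
  (image border included).  This estimator is exact on rasterized shapes and
  biased high on smooth curves relative to continuous arc length; features
  are used comparatively, so the bias is accepted and documented.
* roundness = 4πA/P² under that estimator (a 4×4 square scores π/4, not 1).
* solidity = A / area of the convex hull of the union of pixel squares
  (corner points, not centers), so a single pixel scores exactly 1.
* M20 averages the k = max(1, ⌈0.2·n⌉) largest pixel values.
* An empty cytoplasm/membrane compartment (nucleus fills the cell) yields
  zeros plus a `cyto_empty` flag rather than dropping the cell.

Sizes are in pixels; physical areas derive from the pixel size (0.45 µm/px
at acquisition scale) when needed.

## Normalization

Both stages are per image (sample × field of view) and monotone per marker,
so within-image cell orderings are preserved.

* **NC ratio**: for markers with a declared negative-control channel, every
  intensity feature is divided by the same cell's corresponding NC feature
  (+ eps guard; zero-NC cells flagged `nc_zero`).  NC columns are dropped
  after use.  In the simulator the marker and its NC share a per-cell
  log-normal unspecific factor, making the ratio exactly corrective in
  expectation.
* **Background level**: for each marker with a mutually exclusive
  counterpart, cells above the counterpart's q_counterpart = 0.8 quantile
  (reference feature: M20 in cytoplasm/membrane) form the reference
  population, and the background level b is their q_background = 0.95
  quantile of the marker's reference feature; all intensity features are
  divided by b, putting markers on a common background-relative scale
  (1.0 = background) — which is simultaneously the batch correction.
  Division rather than subtraction keeps features positive; downstream
  z-scoring makes the two equivalent up to affine terms.  Markers with too
  few reference cells (<20) pass through with a warning.  Note the quantile
  semantics: by construction a fraction (1 − q_background) of true
  background cells exceeds b, so b is a normalization scale, not an optimal
  classification threshold; at q = 0.99 it also classifies the synthetic
  two-population fixture at ≥99% accuracy.  The estimator sits behind a
  small config so a model-based alternative can be plugged in.

## Consensus stability and feature validation

A feature-subset variant (I: ME+TO+M20 in all compartments + morphology,
II: M20 + morphology, III: ME + morphology, IV: TO + morphology, V: M20
only) is scored by R repeats (default 100; 20 in the test suite) of:
subsample ⌈0.8·F⌉ feature columns, z-score, embed to 2D by t-SNE
(perplexity 30), fit a G-component Gaussian mixture (G = 10 default) on the
embedding.  The embedding is recomputed inside every repeat — the
subsampled features change it — and every stochastic step draws its seed
from the spec seed.  Co-clustering frequencies form the consensus matrix;
the consensus partition is an average-linkage cut of 1 − consensus into G
groups.  Metrics:

* PAC: fraction of i<j consensus entries strictly inside (0.1, 0.9),
* CON: mean Rand index (pair-agreement) of each repeat's partition against
  the consensus partition,
* MSS: mean silhouette width of the consensus partition under distance
  1 − consensus (self-contained and embedding-independent; a variant on
  z-scored data is a one-line change at the call site),
* MCS = ((1 − PAC) + CON + MSS)/3, bounded in [−1/3, 1], strictly
  decreasing in PAC.

CON and MSS here are this package's definitions; consensus-clustering
packages differ in their internal definitions of the same names, so
absolute MCS values are comparable within this implementation only.
Significance of features across clusters uses one-way ANOVA with
Benjamini–Hochberg correction (α = 0.05); effect size is the max − min of
z-scored cluster means.  PCA runs on autoscaled features (constant columns
dropped with a warning); contributions are squared loadings normalized per
component.

## Atlas

Embedding: t-SNE (PCA initialization, fixed seed) of z-scored features;
fully degenerate input (all cells identical) short-circuits to a
single-point embedding.  Clustering: Gaussian mean shift on a gridded
kernel-density estimate of the embedding (256×256 grid, Gaussian smoothing
at the bandwidth, steepest-ascent pointer per node, pointer doubling to
modes, single-link merge of modes within `mode_merge_tol`), which is
deterministic and O(grid); an exact per-point iteration exists behind a
flag for small inputs and agrees with the grid on the fixtures.  The
default bandwidth is **embedding extent / 6**, calibrated once on the
fixtures: large enough that one Gaussian blob yields one mode, small enough
to keep well-separated t-SNE islands apart (recovered cluster counts are
stable over divisors ~6–12 on the atlas fixture).  Bandwidths of
interactive tools are in tool-internal units and do not transfer.  Cluster
count is non-increasing in bandwidth on the tested grids.  Profiles are
per-cluster medians min-max-scaled per feature to [0, 1] (all-equal medians
map to 0); sub-clustering is complete-linkage agglomeration on Euclidean
distance over the selected normalized features; composition tables report
counts and proportions per sample × cluster with zeros for absent
combinations.

## Simulator scope and what passing tests show

The generator emulates: non-overlapping elliptical nuclei (radius,
eccentricity and a solidity-lowering notch per cell type) with cytoplasm
rings; per-type log-normal expression; per-cell unspecific binding shared
with NC channels; vignetting, bleach residuals, illumination fields, batch
gains; Poisson + Gaussian noise; a deterministic speckle phase-contrast
texture.  The default study conditions are four well-separated types
(tumor-like GD2⁺, T-cell-like CD3⁺, monocyte-like CD14⁺, stromal-like
VIM⁺ with banded nuclei) at ~400 cells per 720 px field (0.45 µm/px), mild
artifacts (α = 0.2, ρ = 0.2, log-sd 0.3 unspecific factor, shot noise on).
The paper-scale acquisition (2018 px, 20 markers, tens of thousands of
cells over eight samples) is represented at reduced size; the desk-scale
problem sizes (256–720 px fields, 40–400 cells, R = 20 repeats) are the
package's chosen test conditions.

Not modelled: point-spread-function blur, chromatic shift, 3D structure,
cell-shape irregularity beyond notched ellipses, overlapping/touching cells
beyond a 2 px clearance, spatially structured autofluorescence, or
marker-correlated segmentation errors.  Passing the recovery tests
therefore shows the pipeline's stages are correct and exactly invert the
artifact model they target — not that real MELC data, whose artifacts are
richer, will reach the same F1/ARI.  The paper-scale headline quantities
(real-data MCS values, a 10-cluster atlas of 35,700 cells, 30 sub-clusters)
depend on the archived dataset and tool-internal definitions and are out of
scope here.

## Numerical conventions

eps guards: flat-field denominator 1e−6 of the brightfield dynamic range;
NC-ratio denominator 1e−6; background level floored at eps when the
reference population is all-zero (flagged).  Bleach subtraction and
flat-field clip at 0.  Degenerate mixture fits in a consensus repeat are
re-seeded once, then the repeat is skipped with a warning; a single-cluster
consensus partition defines MSS = 0 with a warning.  GMS labels are
relabelled 1..K by decreasing size for stable output.  Per-stage seeds are
SHA-256-derived from one global seed (< 2³¹).  Scene placement is
sequential rejection sampling with a 2 px clearance and 200 tries per cell;
failure raises "scene too dense" rather than degrading the geometry.
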