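# Methods

## Scope and data model

The package operates on background-corrected quantitative-phase frames:
2D arrays of optical path delay in radians, one acquisition being a stack
of frames sharing a static background (fixed channel, lens and
illumination alignment). All image coordinates are 0-based (row, col)
with pixel centres at integer positions; this convention is used in every
module.

## Synthetic phantoms

The generator is the package's study-condition definition, not a test
convenience: it fixes the populations on which every downstream claim is
evaluated.

A cell is an anisotropic phase dome on an ellipse footprint. With
semi-axes a = r√e and b = r/√e (r the geometric-mean radius, e ≥ 1 the
axis ratio) and q the normalized ellipse quadratic form in rotated
coordinates, the default parabolic profile is φ = peak · max(0, 1 − q);
a truncated Gaussian profile is also available. The a/b parametrisation
keeps footprint area ≈ πr² independent of elongation, so size and shape
axes are decoupled.

Two default populations span the round-versus-spindle axis the
classifiers must separate:

| parameter (mean ± sd) | epithelial | mesenchymal |
|---|---|---|
| radius r (px) | 9.0 ± 1.2 | 8.0 ± 1.2 |
| elongation e | 1.15 ± 0.10 | 2.60 ± 0.50 |
| peak phase (rad) | 2.5 ± 0.40 | 1.8 ± 0.35 |

Sampled radii are clipped at ≥ 4 px, elongations at ≥ 1, peaks to
[1, 6] rad — suspended tumor cells produce phase peaks well above common
segmentation thresholds, and 6 rad is the top of the nominal phase range.
Frames are 384 × 512 px with 12 cells per frame by default, centre-to-
centre separation ≥ 48 px and a 48 px placement margin (so a 96 × 96
patch window fits around every cell); placement is rejection sampling,
failing loudly when the frame cannot host the request. The background is
one static field per acquisition — three low-order cosine waves
(amplitude ≤ 0.15 rad) plus five Gaussian blemishes (≤ 0.35 rad) —
and per-pixel Gaussian noise (default sd 0.05 rad) is added per frame.
All randomness flows from one integer seed through
`numpy.random.SeedSequence`; identical inputs give bit-identical stacks.

Spike-in scenes allocate classes deterministically: the mesenchymal count
is round-half-even(p·n) (so p = 0.5, n = 7 gives 4), making the designed
mixture fraction an exact quantity rather than a Bernoulli sample.

What the phantoms do *not* emulate: optical diffraction and halo
artifacts, phase wrapping, focus drift, cell–cell contact and clumping,
internal organelle texture, and flow-induced deformation. Passing tests
therefore demonstrate that the pipeline recovers known morphology
differences under realistic noise and background — not that the feature
values numerically match any particular instrument's output.

## Preprocessing

Background: per-pixel median of the first 50 frames, computed once per
acquisition and reused (a warning is emitted and all frames are used when
fewer are available). Subtraction is plain pixelwise difference, no
clipping. Segmentation thresholds the corrected phase strictly above
0.8 rad, labels 8-connected components, fills holes (only outer borders
are meaningful) and extracts the sub-pixel outer polygon by marching
squares; components are ordered by row-major scan order, making the
output deterministic. Contours enclosing strictly more than 30 px of
area ("coverage" is read as enclosed pixel area, not perimeter) are kept;
the 96 × 96 patch is centred on the floor of the area centroid, and
windows crossing the frame border are dropped and counted rather than
zero-padded — truncated cells would corrupt morphology features.
Touching cells merged by the threshold are kept as one object; no
declumping is attempted.

Open choice: whether thresholding precedes or follows background
subtraction is ambiguous in principle; subtraction-first is implemented
(it is listed first in the processing order, and a fixed threshold is
only meaningful on corrected phase).

## Morphology features (set "v1")

Fifteen features per cell span size (area, equivalent diameter,
perimeter), shape (circularity, aspect ratio, eccentricity, solidity,
extent) and phase content (mean/max/sd, optical volume, skewness, radial
profile slope, gradient magnitude mean). Numerical choices that matter:

* **Perimeter** is the length of the marching-squares polygon after a
  cyclic 3-vertex moving average. The raw sub-pixel polygon inflates
  smooth perimeters by ~10% (staircase wiggle), pushing a digital disk's
  circularity to 0.84; the smoothed estimate puts disks at 0.96–0.98.
  The circular convolution is independent of traversal start point and
  exactly equivariant under 90° rotations, so shape features are
  rotation-robust to 1e-9.
* **Second-moment ellipse** adds the unit-pixel-square variance (1/12 per
  axis) to the pixel-centre covariance, so 1-px-wide masks have finite
  aspect ratio (a 5 × 1 bar gives exactly 5).
* **Solidity** is shoelace polygon area over convex-hull polygon area,
  both on the smoothed contour; pixelated hull images systematically
  undershoot for small convex shapes.
* **Degenerate masks** (< 3 px) fail QC with a recorded reason instead of
  emitting NaN silently; skewness of numerically constant phase is
  defined as 0.
* Feature bounds filtering is pass-through by default — no boundary
  values are asserted beyond the upstream 30-px floor, so no cell is
  silently dropped; bounds are configuration.

No claim of numerical equivalence to any external feature catalogue is
made; the set is versioned so an alternative bank can be dropped in.

## Embedding features

The optional 512-d patch embedding uses an 18-layer residual topology
(7×7/2 stem, max-pool, stages 64/128/256/512 of two basic blocks, global
average pooling), implemented directly over numpy with He-initialised
random weights from a seeded generator and per-channel RMS activation
normalisation in place of trained batch-norm statistics. Input patches
are mapped affinely from [−2, 6] rad to [0, 1] and replicated to three
channels; 96 × 96 inputs are fed directly (the backbone is fully
convolutional). Random convolutional projections preserve coarse
structure and are fully reproducible; the discriminative signal in the
default pipeline is carried by the morphology bank, which is why the
pipeline's classification claims are stated for morphology features.
Trained natural-image weights are not bundled; requesting them raises an
actionable error.

## Classification

Fixed configurations (no hyperparameter search): random forest with 100
trees and unbounded depth; SVM with RBF kernel, C = 1, one-against-one;
k-NN with k = 5 and Euclidean distance (vote ties resolve to the lowest
class index); neural network with one hidden layer of 100 units,
cross-entropy loss, Adam, batch size 256, epoch cap 300 with plateau
early stopping (tolerance 1e-4, patience 10), seeded initialisation.
Balancing is seeded random undersampling to the minority class (avoids
synthetic-oversampling artifacts in accuracy estimates) and precedes fold
assignment; folds are stratified (prevents degenerate folds after
balancing) and seeded. Features are z-scored inside each training fold
for SVM/k-NN/NN; trees consume raw features. Accuracy is plain fraction
correct per held-out fold; reports carry all five fold values plus
median and quartiles.

A note on null calibration: under label permutation the mean of
cross-validated accuracies has larger variance than a binomial proportion
on the same number of held-out predictions, because predictions share
training folds. Null-calibration checks therefore use a simulation-derived
band (≈ ±0.05 at n = 1000) rather than the naive binomial band.

Mixture quantification is the predicted-label census: fraction_c =
#(predicted c)/n over the mixed cells, with the classifier trained on
pure populations only.

## Heterogeneity, embedding, dendrograms

All cells of one comparison are z-scored and embedded jointly by UMAP
(n_neighbors = 15, min_dist = 0.1, fixed seed, 2 components). Exactly
duplicated feature rows are mapped to identical coordinates (the fit runs
on unique rows and broadcasts back); otherwise the stochastic layout
would jitter duplicates apart. "Cluster" means the sample label (cell
line / organoid line / condition), not an unsupervised cluster. The
heterogeneity score of cell i is d_i = ‖x_i − c‖² with c the mean
embedding coordinate of the cell's own sample; the per-sample score is
the arithmetic mean. UMAP coordinates carry arbitrary scale, so scores
are comparable only within one fitted embedding; the comparison API
refuses cross-embedding input. The score is exactly translation-invariant
and scales quadratically with coordinate scale.

Feature selection for dendrograms takes the top 26 features by
random-forest impurity importance (descending, ties broken by name).
Each sample is represented by the median vector of its cells over the
selected standardized features; samples agglomerate by single linkage on
Euclidean distances, whose merge heights provably equal the minimum-
spanning-tree edge weights of the representative graph — used as an
independent test oracle. Dendrograms export to Newick.

Density contours are per-group bivariate Gaussian KDEs evaluated on a
shared 128² grid padded 20% beyond the data range; contour levels are
highest-density levels enclosing 25/50/75% of probability mass, and the
grid integral is checked against 1 within 1%. Degenerate (coincident)
groups are skipped with a warning.

Group tests on per-cell scores: two-sided Mann–Whitney U for two groups;
Kruskal–Wallis plus Dunn's post-hoc (tie-corrected rank z-tests,
Bonferroni-adjusted across pairs) for more. The Dunn adjustment method is
a package choice and is recorded in the output.

## Pipeline and reproducibility

The orchestrator derives per-stage seeds from one global seed via
`SeedSequence(global_seed, spawn_key=(stage_index,))`, records them in the
manifest together with per-stage counts (frames, contours, >30 px
survivors, area and border rejections, cells classified), and satisfies
survivors + rejections = contours detected. Identical config and seed
reproduce the feature CSV byte-for-byte. The embedding stage is opt-in;
classification runs when ground-truth or user labels give at least two
classes with ≥ 10 cells each.

## Problem sizes

Automated checks run at desk scale, chosen as the package's validation
conditions: spike-in recovery with 1000 cells per pure population and per
mixture; segmentation recovery on 500 cells; null calibration on 1000
cells; dispersion monotonicity on 3 × 150 cells through a joint UMAP;
end-to-end determinism on 2000 cells. The per-mixture recovery errors at
these sizes are a few tenths of a percentage point.

## Known limitations

* Phantom realism is deliberately limited (no optics simulation); see
  above for what passing tests do and do not show.
* Touching cells are not declumped; merged objects inflate area features
  and are only flagged, not resolved.
* The morphology bank is a canonical reconstruction, not a port of any
  instrument vendor's feature list.
* Heterogeneity scores inherit UMAP's scale arbitrariness; only
  within-embedding comparisons are meaningful, and the API enforces this.
* The seeded-random embedding is reproducible but untrained; it is not a
  substitute for learned representations when real image data are
  available.
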