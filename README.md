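# dhm-pheno

Label-free single-cell phenotyping of quantitative-phase images from
digital holographic microscopy (DHM), for groups studying
epithelial–mesenchymal plasticity and intratumoral heterogeneity in
suspended tumor cells (dissociated cell lines, patient-derived organoids)
imaged in microfluidic flow.

A DHM phase image assigns each pixel the optical path delay φ(r, c) in
radians induced by the specimen — a proxy for local dry mass. Frames
(nominally 512 × 384 px, values typically in [−2, 6] rad) contain multiple
suspended cells. The package implements the downstream computational
pipeline:

1. **Preprocessing** — the static channel background is estimated once per
   acquisition as the per-pixel median of the first *n* = 50 frames and
   subtracted; cells are segmented by binary thresholding of the corrected
   phase (φ > 0.8 rad), outer contours of 8-connected components are
   extracted, and every contour enclosing more than 30 px is stored with
   the 96 × 96 px patch around its area centroid.
2. **Features** — a versioned bank of 15 morphological descriptors per
   cell (area, polygonal perimeter, circularity 4πA/P², second-moment
   ellipse aspect ratio and eccentricity, solidity, extent, phase
   statistics, optical volume Σφ, radial profile slope, gradient texture),
   optionally concatenated with a 512-d embedding from an 18-layer
   residual convolutional backbone (seeded random weights).
3. **Classification** — balanced (random undersampling), stratified 5-fold
   cross-validation with four fixed configurations: random forest (100
   trees, unbounded depth), RBF-kernel SVM (C = 1, one-against-one), k-NN
   (k = 5), and a single-hidden-layer neural network (100 units, Adam,
   batch 256). Spike-in quantification trains on pure populations and
   reports predicted class fractions in mixtures.
4. **Heterogeneity** — joint 2D UMAP of all cells of a comparison, per
   sample the tumor heterogeneity score d_i = ‖x_i − c‖² (squared distance
   of cell i to its sample centroid c in the embedding; per-sample score Ø
   = mean d_i), single-linkage dendrograms over the 26 most important
   features (random-forest importance), bivariate-KDE density contours,
   and Mann–Whitney / Kruskal–Wallis + Dunn group tests on the scores.

Because no public DHM image data accompany the method, the package ships a
first-class **synthetic phantom generator**: anisotropic phase domes on
ellipse footprints emulate round/compact (epithelial-like) versus
elongated/spindle (mesenchymal-like) cells on a static artifact background
with pixel noise, with exact per-cell masks, centroids and labels. Every
stage is tested against this ground truth.

## Worked example

```python
import numpy as np
from dhmpheno import (render_spike_in, extract_cells, compute_features,
                      ClassifierSpec, balance_classes, cross_validate)
from dhmpheno.phantoms import match_to_truth

# 50/50 two-population scene: 400 cells with exact ground truth
frames, truth, _ = render_spike_in(p_mesenchymal=0.5, n_cells=400, seed=1)

cells = extract_cells(frames)          # background, threshold, patches
vectors = [compute_features(p) for p in cells.patches]
X = np.array([v.as_array() for v in vectors if v.qc_pass])
y = np.array(match_to_truth([p.centroid for p in cells.patches],
                            [p.frame_id for p in cells.patches], truth))

Xb, yb, _ = balance_classes(X, y, seed=0)
report = cross_validate(Xb, yb, ClassifierSpec("random_forest", seed=0))
print(np.round(report.fold_accuracies, 3))
```

Output:

```
34 frames of 384x512 px, 400 cells
401 contours, 396 cells kept (>30 px, window in bounds)
feature matrix (396, 15), classes {'epithelial': 197, 'mesenchymal': 199}
5-fold accuracies: [1.    1.    0.987 1.    1.   ]
median 1.000, quartiles [1. 1.]
```

396 of 400 simulated cells survive segmentation and filtering (one pair of
close domes merges into a 401st contour; a few small or border-adjacent
cells are dropped), and the two morphological populations — which differ
mainly in axis ratio — are separated almost perfectly by the forest on the
held-out folds.

The same stages are scriptable from the shell:

```sh
dhm-pheno simulate --out scene --seed 1 --n-cells 400
dhm-pheno preprocess --in scene/frames.tif --out patches
dhm-pheno features --patches patches --out features.csv
dhm-pheno run --config pipeline.yaml     # full pipeline + manifest
```

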