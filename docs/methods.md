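# Methods

`nodecad` implements a two-stage computer-aided detection (CAD) pipeline
for lymph nodes in co-registered 3D MR Lymphography (MRL) volumes, together
with the FROC-based statistical machinery used to evaluate and compare
detection systems, and a synthetic phantom generator that makes the whole
pipeline trainable and measurable without patient data.

## The detection model

### Stage 1 — candidate detection

Per-voxel features are computed from the two input channels (a T1-weighted
"VIBE"-like channel in which nodes are bright, and a T2\*-weighted
"MEDIC"-like channel):

* **Standardized intensities.** Each volume is rescaled by its own mean µ
  and population standard deviation σ: `I' = (I − µ)/σ`. A constant volume
  (σ = 0) is rejected as degenerate.
* **Hessian shape features.** Blobness, vesselness and sheetness maps from
  the eigenvalues |λ1| ≤ |λ2| ≤ |λ3| of the Gaussian-smoothed, γ=2
  scale-normalized Hessian, at scales {1.6, 2.4, 3.2} mm (bracketing the
  3–10 mm node size range), aggregated over scales by maximum. The maps are
  Frangi-style products of eigenvalue-ratio terms and a second-order
  structureness term `1 − exp(−S²/2c²)`, with α = β = 0.5 and `c` set
  per volume and scale to half the maximum Frobenius norm of the Hessian.
  All maps are bounded to [0, 1] and are zero for the wrong eigenvalue
  signs (bright-structure polarity; configurable per channel).
* **Positional features.** Normalized grid coordinates per axis (each in
  [0, 1]) plus, when landmark masks are supplied, a signed Euclidean
  distance map per landmark (negative inside). These stand in for
  atlas-registration position features, which require real pelvic anatomy;
  the phantoms have none.

A **GentleBoost** classifier with regression stumps (200 rounds by
default) maps feature rows to an additive score `F`. Each round fits, by
exhaustive search over features and midpoint thresholds between
consecutive sorted unique values, the stump minimizing the weighted
squared error to labels y ∈ {−1, +1}, where each side's response is the
weighted mean of y on that side; weights update as `w ← w·exp(−y f)` with
renormalization. The score maps to a voxel likelihood through the
logistic link `p = 1/(1 + e^{−2F})`, the standard calibration for
additive logistic models (the link is a design choice; only the ranking
matters for FROC analysis).

The **voxel training set** takes positives only from nodes of volume
≥ 0.1 ml (195 voxels at 0.8 mm) and only within 4 mm of the node's center
of gravity — boundary voxels carry partial-volume and annotation error —
and an equal number of background voxels drawn uniformly at random.

**Candidates** are the local maxima of the likelihood map under a
spherical window of 10 mm diameter (the maximum size of non-enlarged
lymph nodes): voxel v is a maximum iff its likelihood is ≥ that of every
voxel whose center lies within 5 mm, and exceeds a floor (0.01 by
default; without a floor the all-background plateau produces spurious
candidates). Plateaus — 26-connected components of tied maxima, compared
with exact float equality since plateaus arise from identical computation
paths — are reduced to the member voxel nearest their center of gravity,
ties broken lexicographically.

### Stage 2 — multi-view CNN false-positive reduction

Around every candidate, 65 × 65 patches (0.8 mm pitch, hence a
52 × 52 mm field of view) are resliced by trilinear interpolation on the
nine symmetry planes of a cube: three axis-aligned planes (view 0 is the
original/coronal image plane) and six edge-diagonal planes whose in-plane
axes are a face diagonal and the orthogonal coordinate axis. The in-plane
sample step is the voxel pitch for all views, so every view shares one
scale; samples outside the volume are zero-padded (zero is the
standardized background mean). View subsets are nested: 1-view = {0},
3-view = {0, 1, 2}, 9-view = all nine. Patches are taken from the
standardized T1-like channel (configurable).

The network has one independent convolutional branch per view (no weight
sharing, so each view learns its own filters): conv 5×5×24 → max-pool 2×2
→ conv 5×5×48 → max-pool 2×2 → conv 5×5×96, ReLU after every convolution,
no padding, stride-1 convolutions; for a 65×65 input the spatial trace is
61 → 30 → 26 → 13 → 9. Branch outputs are concatenated along the feature
dimension (n_views · 9 · 9 · 96) into a 512-unit fully-connected ReLU
layer with 20 % dropout and a 2-way softmax.

Training uses plain SGD with Nesterov momentum 0.9, learning rate 1e-4,
categorical cross-entropy plus an L2 penalty λ₂ = 0.0005 on weights (not
biases), and mini-batches of 32 patch sets with exactly 16 per class,
sampled with replacement from the training pool. An epoch is 200
mini-batches; training runs at most 200 epochs and stops once the
full-validation-set accuracy (threshold 0.5) has not improved for more
than 20 epochs, restoring the best-epoch weights. Weight initialization
is He-uniform with zero biases, seed-controlled.

The network is implemented directly on numpy: convolutions as im2col
patch matrices multiplied through BLAS, the input gradient as k² shifted
matrix products, max-pooling with cached argmax, inverted dropout.
Analytic gradients are verified against central finite differences in the
test suite, and a single SGD step is checked to reduce the batch loss.

The **CNN training set** contains all annotated nodes — each detected
node's best candidate, plus a pseudo-candidate at the center of gravity
of every node stage 1 missed — and a seeded random subset of the stage-1
false positives. Mini-batch balancing handles the residual class skew.

## Evaluation

A candidate whose voxel lies inside a node's segmentation is a hit; the
highest-scoring hit represents the node and surplus hits count neither as
true nor as false positives; everything else is a false positive. The
FROC curve records, at every distinct score threshold, the fraction of
annotated nodes detected versus false positives per node and per image.
The figure of merit is the partial area under the FROC curve between 0.25
and 32 false positives per node — trapezoidal integration of sensitivity
(as a fraction) against FP/node on a linear axis, linearly interpolated
at the bounds and step-extended with the last sensitivity beyond the last
operating point; the maximum attainable value is 31.75.

Uncertainty is assessed by resampling patients with replacement (1000
replicates by default, seeded); confidence bands are the 2.5/97.5
percentiles of sensitivity at fixed FP/node abscissae. Systems are
compared with a **paired one-sided bootstrap test**: all systems are
re-evaluated on the same resampled patients per replicate, and the raw p
for "B beats A" is the fraction of replicates in which B does not,
with ties half-weighted and the (count+1)/(n+1) small-sample correction.
Half-weighting ties makes the test behave sensibly when two systems are
literally identical (p ≈ 0.5 rather than 1) and coincides with the plain
count for continuous pAUC distributions. Multiple comparisons are
Bonferroni-corrected (`min(1, raw·m)`).

Cross-validation is at the patient level: patients sorted by annotated
node count (ties shuffled by seed) are assigned greedily to the lightest
of five folds, so folds carry near-equal node counts. Each run trains on
three folds, validates on one, tests on one; pooled test-fold predictions
over the five runs feed the statistical analysis. Stage 1 is retrained
within each run on the training folds, so neither stage ever sees its
test fold.

## The phantom generator

Each phantom is a pair of co-registered isotropic volumes (0.8 mm,
64³ voxels by default) emulating the two MRL channels, plus an integer
node label map. Scenes contain: ellipsoidal nodes with major diameter
drawn uniformly from 3–10 mm, random orientation and mild random
flattening, placed without overlap (labels 1..n, every label non-empty);
curved vessel-like tubes swept along smoothed random polylines spanning
the volume, so they intersect the sampling planes both longitudinally and
transversally — the structures a nodular-blob detector confuses with
nodes; one thin slab emulating fascia-like sheets; channel-wise intensity
offsets over a constant background; and additive Gaussian noise. The
T2\*-like channel shares the geometry with independent contrasts;
hypointense-node simulation is available but off by default. World
coordinates follow the voxel-center convention used everywhere in the
package: index i sits at (i + 0.5)·spacing.

Defaults (5 nodes, 3 vessels, 1 sheet, node contrast 1.0/0.6, vessel
0.85/0.9, background 0.2, noise SD 0.05) were chosen once as a plausible
contrast-to-noise regime for USPIO-era pelvic MRL at desk scale.

What the phantoms do **not** model: MR physics, bias fields, contrast
uptake kinetics, anatomy (organs, fat planes, bone), inter-patient
variability of structure counts, or annotation error. Passing tests on
phantoms therefore demonstrate that the pipeline's machinery is correct
and that the multi-view CNN can exploit 3D shape to reject tubular false
positives; they do not certify clinical-grade performance on patient
images.

A noteworthy consequence of the method's per-volume adaptive scaling:
a structure-free noise-only volume is standardized to unit variance and
its strongest noise bumps then look locally structured, so a trained
stage-1 detector still emits candidates on an empty phantom. This mirrors
the false-positive problem the second stage exists to fix.

## Problem sizes and numerical choices

The bundled experiment (`nodecad.pipeline.reduced_scale_config`, used by
`scripts/acceptance.py` and the acceptance tests) runs the full
5-fold-cross-validated two-system comparison on 20 phantoms of 64³ voxels
with the reference values for every method parameter (200 boosting
rounds, 10 mm maxima window, 65×65 patches, the full three-conv-branch
network, lr 1e-4, momentum 0.9, λ₂ 5e-4, dropout 0.2, batch 32, balanced
mini-batches, pAUC over 0.25–32 FP/node, 1000 bootstrap replicates); only
the cohort size and the CNN iteration count (3 epochs × 20 mini-batches
per cross-validation run) are reduced to single-CPU scale. On this easy,
cleanly separable synthetic task that schedule is ample for the CNN to
rank nodes above tubes; the improvement direction it demonstrates is
stable across seeds.

Other numerical choices: plateau equality is exact float equality;
stump thresholds are midpoints of consecutive sorted unique values;
boosting is deterministic given row order; patch interpolation is
trilinear with zero padding; all randomness flows from one global seed
through fixed per-module offsets (`nodecad.config.module_seed`), making
the full pipeline bit-reproducible.

## Known limitations

* The CNN runs on the CPU via numpy; it is adequate for the bundled
  problem sizes, not for 320×320×90 patient volumes at full training
  scale.
* Atlas-based positional features are reduced to coordinates/landmark
  distances; no deformable registration is provided.
* The FROC hit criterion (candidate voxel inside the segmentation) is a
  standard convention; the evaluation does not implement alternative
  figures of merit (e.g. JAFROC) or size-stratified analyses.
* 9-view support is implemented and tested, but the bundled experiment
  compares only the candidate detector and the 3-view system to stay
  within desk-scale runtimes.
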