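# nodecad

Two-stage lymph-node detection for 3D pelvic MR Lymphography (MRL)
volumes, with bootstrapped FROC evaluation and a synthetic phantom
generator, for researchers building or benchmarking computer-aided
detection (CAD) pipelines on dual-channel MR data.

MRL (MRI with a USPIO contrast agent) shows every pelvic lymph node —
healthy or metastatic — but reading a study takes experts the better part
of an hour. A CAD system that proposes all node locations for review must
be highly sensitive, which makes its false-positive rate the limiting
factor: nodes and blood vessels both look like bright blobs in any single
2D plane. This package implements the two-stage answer:

1. **Candidate detection.** Per-voxel features — channel intensities
   standardized as (I − µ)/σ per volume, Hessian-eigenvalue blobness /
   vesselness / sheetness at scales bracketing the 3–10 mm node range, and
   positional maps — feed a GentleBoost classifier (200 regression
   stumps), whose additive score F becomes a node likelihood
   p = 1/(1 + e^(−2F)). Candidates are spherical-window local maxima
   (10 mm diameter) of the likelihood map, with tied plateaus merged by
   26-connected components and reduced to the voxel nearest the centroid.
2. **False-positive reduction.** Around each candidate, 65 × 65 patches
   (52 × 52 mm at 0.8 mm pitch) are resliced on 1, 3 or 9 symmetry planes
   of an enclosing cube and scored by a multi-view CNN — one unshared
   convolutional branch per view (5×5×24 → pool → 5×5×48 → pool → 5×5×96,
   ReLU), concatenated into FC-512 and a 2-way softmax — trained with SGD
   (Nesterov momentum 0.9, lr 1e-4, λ₂ = 5e-4, 20 % dropout), balanced
   16+16 mini-batches and early stopping on validation accuracy. Because
   the oblique views see a vessel lengthwise where a node stays compact,
   the network separates tubular from nodular structures that are
   indistinguishable in-plane.

Systems are compared by FROC analysis: sensitivity (fraction of annotated
nodes detected, one hit per node) versus false positives per node/image,
the partial area under the curve (pAUC) over 0.25–32 FP/node (maximum
31.75), patient-level bootstrap confidence bands, and a paired one-sided
bootstrap test with Bonferroni correction, all under patient-level
stratified 5-fold cross-validation.

No patient data ships with the package; a phantom module generates
dual-channel volumes with ellipsoidal nodes, curved vessel-like tubes,
thin sheets and noise, with ground-truth label maps, so the whole
pipeline is trainable and measurable end to end.

## Worked example

Train stage 1 on two phantoms, detect on a third
(`examples/02_stage1_candidates.py`):

```text
likelihood range: 7.85e-143 .. 1
122 candidates; 5/5 nodes hit, 117 false positives
```

All five nodes receive a candidate inside their segmentation, at the cost
of 117 false positives — the stage-2 problem. Train the multi-view CNN on
a node-like-vs-vessel-like patch task (`examples/04_train_false_positive_reduction.py`):

```text
 epoch  train_loss  val_accuracy
     1    1.045510           1.0
     ...
mean node-class probability: blobs 0.951, bars 0.048
```

The score gap (0.95 vs 0.05) is what rescoring the 122 candidates with
the CNN exploits: ranked by CNN probability instead of stage-1
likelihood, vessel hits drop below the node hits and the FROC curve
shifts left. The remaining examples cover phantom generation, the nine
view bases and patch geometry, and the bootstrap FROC comparison.

A command-line interface wraps the same pipeline for on-disk datasets
(NIfTI volumes, CSV candidate tables, JSON reports):

```sh
nodecad simulate --out data --n-phantoms 20 --seed 1
nodecad detect --data data --out cands
nodecad reduce-fp --data data --candidates cands --n-views 3 --out scored
nodecad evaluate --data data --system cd=cands --system 3view=scored --out report.json
```

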