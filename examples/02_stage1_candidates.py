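"""Stage 1: per-voxel features, GentleBoost likelihood, candidate maxima.

Trains the boosted voxel classifier on two phantoms and detects candidates
on a third, then reports how many annotated nodes received a candidate
inside their segmentation (true positives) and how many candidates landed
in background (false positives for the second stage to remove).
"""

from nodecad import (
    PhantomConfig,
    build_voxel_training_set,
    compute_default_features,
    detect_candidates,
    fit_gentleboost,
    generate_phantom,
    match_candidates,
    predict_likelihood,
)
import numpy as np

train_phantoms = [generate_phantom(PhantomConfig(seed=s)) for s in (1, 2)]
test_phantom = generate_phantom(PhantomConfig(seed=3))

rows, labels = [], []
for ph in train_phantoms:
    fs = compute_default_features(ph.t1_like, ph.t2s_like)
    X, y = build_voxel_training_set(fs, ph.annotation, rng_seed=0, max_per_class=800)
    rows.append(X)
    labels.append(y)
model = fit_gentleboost(np.concatenate(rows), np.concatenate(labels), n_rounds=200)

features = compute_default_features(test_phantom.t1_like, test_phantom.t2s_like)
likelihood = predict_likelihood(model, features)
candidates = match_candidates(
    detect_candidates(likelihood, window_diameter_mm=10.0, floor=0.01),
    test_phantom.annotation,
)

hits = {c.node_label for c in candidates if c.node_label is not None}
fps = sum(c.node_label is None for c in candidates)
n_nodes = len(test_phantom.annotation.node_labels())
print(f"likelihood range: {likelihood.data.min():.3g} .. {likelihood.data.max():.3g}")
print(f"{len(candidates)} candidates; {len(hits)}/{n_nodes} nodes hit, {fps} false positives")
print("The high FP count is expected: the candidate detector is tuned for "
      "sensitivity, and the multi-view CNN exists to cut the FPs down.")
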