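"""Stage-1 candidate detection: boosted voxel classification + local maxima.

A GentleBoost classifier with regression stumps (200 rounds by default)
turns the per-voxel feature stack into a lymph-node likelihood in [0, 1].
Candidates are the local maxima of the likelihood map under a spherical
window of 10 mm diameter -- the maximum size of non-enlarged lymph nodes --
with plateau-shaped maxima merged by 26-connected component analysis and
reduced to the voxel nearest the plateau's center of gravity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FeatureStack
from .phantom import node_properties
from .volume import AnnotationMap, ImageVolume

MIN_NODE_VOLUME_ML = 0.1  # nodes below this are excluded from voxel training
COG_RADIUS_MM = 4.0  # positives must lie within this radius of the node center


@dataclass
class Stump:
    """Depth-1 regression tree on one feature: respond by threshold side."""

    feature_index: int
    threshold: float
    response_ge: float
    response_lt: float

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.feature_index]
        return np.where(col >= self.threshold, self.response_ge, self.response_lt)


@dataclass
class BoostModel:
    stumps: list[Stump]
    n_rounds: int = 200
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.stumps) > self.n_rounds:
            raise ValueError("more stumps than boosting rounds")

    def decision_function(self, X: np.ndarray, chunk: int = 65536) -> np.ndarray:
        """Additive score F(x) = sum of stump responses, vectorized."""
        if not self.stumps:
            return np.zeros(len(X))
        idx = np.array([s.feature_index for s in self.stumps])
        thr = np.array([s.threshold for s in self.stumps])
        ge = np.array([s.response_ge for s in self.stumps])
        lt = np.array([s.response_lt for s in self.stumps])
        F = np.empty(len(X))
        for start in range(0, len(X), chunk):
            block = X[start : start + chunk][:, idx]
            F[start : start + chunk] = np.where(block >= thr, ge, lt).sum(axis=1)
        return F

    def to_json(self, path: str) -> None:
        payload = {
            "n_rounds": self.n_rounds,
            "feature_names": self.feature_names,
            "stumps": [vars(s) for s in self.stumps],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "BoostModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            stumps=[Stump(**s) for s in payload["stumps"]],
            n_rounds=payload["n_rounds"],
            feature_names=payload.get("feature_names", []),
        )


@dataclass
class Candidate:
    """A stage-1 detection point, optionally rescored by the stage-2 CNN."""

    voxel_index: tuple[int, int, int]
    position_mm: np.ndarray
    likelihood: float
    cnn_probability: float | None = None
    node_label: int | None = None

    def score(self, system: str = "stage1") -> float:
        if system == "stage1":
            return self.likelihood
        if self.cnn_probability is None:
            raise ValueError("candidate has no CNN probability")
        return self.cnn_probability


class EmptyClassError(ValueError):
    pass


def build_voxel_training_set(
    features: FeatureStack,
    annotation: AnnotationMap,
    rng_seed: int,
    max_per_class: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced voxel training rows (labels +1 node / -1 background).

    Positive voxels come only from nodes of volume >= 0.1 ml and must lie
    within 4 mm of that node's center of gravity (excluding boundary voxels
    guards against partial-volume and annotation errors).  Background
    voxels are drawn uniformly; class counts are equal.
    """
    if features.shape != annotation.shape:
        raise ValueError("features and annotation must share the grid")
    rng = np.random.default_rng(rng_seed)
    s = annotation.spacing_mm
    pos_mask = np.zeros(annotation.shape, dtype=bool)
    for prop in node_properties(annotation):
        if prop.volume_ml < MIN_NODE_VOLUME_ML:
            continue
        idx = np.argwhere(annotation.labels == prop.label)
        centers_mm = (idx + 0.5) * s
        near = np.linalg.norm(centers_mm - prop.center_mm, axis=1) <= COG_RADIUS_MM
        sel = idx[near]
        pos_mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    pos_flat = np.flatnonzero(pos_mask.ravel())
    if len(pos_flat) == 0:
        raise EmptyClassError(
            "no eligible positive voxels (all nodes < 0.1 ml or absent)"
        )
    bg_flat = np.flatnonzero((annotation.labels == 0).ravel())
    n = min(len(pos_flat), len(bg_flat))
    if max_per_class is not None:
        n = min(n, max_per_class)
    pos_sel = rng.choice(pos_flat, size=n, replace=False)
    neg_sel = rng.choice(bg_flat, size=n, replace=False)
    X = features.as_matrix()
    rows = np.concatenate([pos_sel, neg_sel])
    y = np.concatenate([np.ones(n), -np.ones(n)])
    return X[rows], y


def _best_stump(X, y, w, sort_idx):
    """Exhaustive weighted-least-squares stump search, vectorized per feature.

    Thresholds are midpoints between consecutive sorted unique feature
    values; each side's response is the weighted mean of y on that side.
    """
    n, p = X.shape
    total_w = w.sum()
    total_wy = (w * y).sum()
    best = (np.inf, None)
    for j in range(p):
        order = sort_idx[:, j]
        xs = X[order, j]
        ws = w[order]
        wys = (w * y)[order]
        w_lt = np.cumsum(ws)[:-1]
        s_lt = np.cumsum(wys)[:-1]
        valid = xs[:-1] < xs[1:]
        if not valid.any():
            continue
        w_ge = total_w - w_lt
        s_ge = total_wy - s_lt
        # weighted SSE = sum(w*y^2) - s_lt^2/w_lt - s_ge^2/w_ge; the first
        # term is split-independent, so minimize the negative gain
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(
                valid & (w_lt > 0) & (w_ge > 0),
                s_lt**2 / w_lt + s_ge**2 / w_ge,
                -np.inf,
            )
        k = int(np.argmax(gain))
        if gain[k] == -np.inf:
            continue
        err = (w * y * y).sum() - gain[k]
        if err < best[0] - 1e-15:
            thr = 0.5 * (xs[k] + xs[k + 1])
            best = (
                err,
                Stump(
                    feature_index=j,
                    threshold=float(thr),
                    response_ge=float(s_ge[k] / w_ge[k]),
                    response_lt=float(s_lt[k] / w_lt[k]),
                ),
            )
    if best[1] is None:
        raise ValueError("no valid split found (all features constant)")
    return best[1]


def fit_gentleboost(
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int = 200,
    feature_names: list[str] | None = None,
) -> BoostModel:
    """Classic GentleBoost with regression stumps.

    Weights start uniform; each round fits the stump minimizing the
    weighted squared error to y in {-1,+1}, adds it to the ensemble, and
    reweights w <- w * exp(-y f(x)), renormalized.  Deterministic given
    the input row order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1.0, 1.0))):
        raise ValueError("labels must be -1/+1")
    if len(classes) < 2:
        raise ValueError("need at least one example of each class")
    n = len(y)
    w = np.full(n, 1.0 / n)
    sort_idx = np.argsort(X, axis=0, kind="stable")
    stumps: list[Stump] = []
    for _ in range(n_rounds):
        stump = _best_stump(X, y, w, sort_idx)
        f = stump.evaluate(X)
        stumps.append(stump)
        w = w * np.exp(-y * f)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            break
        w /= total
    return BoostModel(stumps, n_rounds=n_rounds, feature_names=feature_names or [])


def predict_likelihood(model: BoostModel, features: FeatureStack) -> ImageVolume:
    """Map the additive boosting score F to [0, 1] via logistic(2F)."""
    if model.feature_names and model.feature_names != features.names:
        raise ValueError("feature stack does not match the model's feature space")
    X = features.as_matrix()
    F = model.decision_function(X)
    lik = 1.0 / (1.0 + np.exp(-2.0 * F))
    return ImageVolume(lik.reshape(features.shape), features.spacing_mm)


def _spherical_footprint(radius_mm: float, spacing_mm: float) -> np.ndarray:
    r_vox = radius_mm / spacing_mm
    ir = int(np.floor(r_vox))
    offs = np.arange(-ir, ir + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    return (oz**2 + oy**2 + ox**2) <= r_vox**2 + 1e-12


def detect_candidates(
    likelihood: ImageVolume,
    spacing_mm: float | tuple | None = None,
    window_diameter_mm: float = 10.0,
    floor: float = 0.01,
) -> list[Candidate]:
    """Spherical-window local maxima of the likelihood map.

    A voxel is a maximum iff its likelihood is >= that of every voxel whose
    center lies within window_diameter/2 (Euclidean, mm) and exceeds
    ``floor``.  26-connected plateaus of tied maxima are merged and
    represented by the member voxel nearest the plateau's center of
    gravity (ties broken by lexicographic voxel index).
    """
    if spacing_mm is None:
        spacing_mm = likelihood.spacing_mm
    spacing_arr = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing_arr.size > 1 and not np.allclose(spacing_arr, spacing_arr[0]):
        raise ValueError("only isotropic spacing is supported")
    s = float(spacing_arr[0])
    L = likelihood.data
    fp = _spherical_footprint(window_diameter_mm / 2.0, s)
    local_max = ndimage.maximum_filter(L, footprint=fp, mode="constant", cval=-np.inf)
    is_max = (L >= local_max) & (L > floor)
    labels, n_comp = ndimage.label(is_max, structure=np.ones((3, 3, 3), dtype=int))
    candidates: list[Candidate] = []
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labels == comp)  # lexicographic row order
        cog = members.mean(axis=0)
        d2 = ((members - cog) ** 2).sum(axis=1)
        pick = members[int(np.argmin(d2))]  # argmin keeps the first (lex) tie
        idx = tuple(int(v) for v in pick)
        candidates.append(
            Candidate(
                voxel_index=idx,
                position_mm=(np.asarray(idx, dtype=float) + 0.5) * s,
                likelihood=float(L[idx]),
            )
        )
    candidates.sort(key=lambda c: (-c.likelihood, c.voxel_index))
    return candidates


def candidates_to_csv(candidates: list[Candidate], path: str) -> None:
    rows = [
        {
            "index_x": c.voxel_index[0],
            "index_y": c.voxel_index[1],
            "index_z": c.voxel_index[2],
            "pos_mm_x": c.position_mm[0],
            "pos_mm_y": c.position_mm[1],
            "pos_mm_z": c.position_mm[2],
            "likelihood": c.likelihood,
            "cnn_probability": c.cnn_probability,
            "node_label": c.node_label,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "index_x", "index_y", "index_z",
            "pos_mm_x", "pos_mm_y", "pos_mm_z",
            "likelihood", "cnn_probability", "node_label",
        ],
    ).to_csv(path, index=False)


def candidates_from_csv(path: str) -> list[Candidate]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Candidate(
                voxel_index=(int(row.index_x), int(row.index_y), int(row.index_z)),
                position_mm=np.array([row.pos_mm_x, row.pos_mm_y, row.pos_mm_z]),
                likelihood=float(row.likelihood),
                cnn_probability=None
                if pd.isna(row.cnn_probability)
                else float(row.cnn_probability),
                node_label=None if pd.isna(row.node_label) else int(row.node_label),
            )
        )
    return out
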