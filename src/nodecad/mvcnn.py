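"""Multi-view convolutional network for false-positive reduction.

One independent 2D branch per sampling plane (weights are not shared
between views, so each branch learns filters for its own view):

    input 65x65x1
    -> conv 5x5, 24 ch, stride 1, no padding -> 61x61x24, ReLU
    -> max-pool 2x2 stride 2                 -> 30x30x24
    -> conv 5x5, 48 ch                       -> 26x26x48, ReLU
    -> max-pool 2x2 stride 2                 -> 13x13x48
    -> conv 5x5, 96 ch                       -> 9x9x96, ReLU

Branch feature maps are concatenated along the feature dimension and fed
to a fully-connected layer of 512 units (ReLU, 20% dropout) and a 2-way
softmax output.  Training uses stochastic gradient descent with Nesterov
momentum, categorical cross-entropy plus an L2 weight penalty, and
class-balanced mini-batches; early stopping monitors validation accuracy.

The network is implemented directly on numpy (im2col convolutions backed
by BLAS matrix products); gradients are exercised by numeric checks in
the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multiview import PatchSet
from .phantom import node_properties
from .stage1 import Candidate
from .volume import AnnotationMap

# ---------------------------------------------------------------------------
# layers


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N, H-k+1, W-k+1, k, k, C) patch matrix (copied)."""
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((n, oh, ow, k, k, c), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, :, a, b, :] = x[:, a : a + oh, b : b + ow, :]
    return cols


class Conv2D:
    """Valid 5x5 convolution, stride 1, channels-last."""

    def __init__(self, cin, cout, k=5, rng=None, first=False):
        self.k, self.cin, self.cout = k, cin, cout
        self.first = first  # input layer: skip the input gradient
        self.W = _he_uniform(rng, (k, k, cin, cout), k * k * cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cols = None
        self._xshape = None

    def forward(self, x, train=False):
        cols = _im2col(x, self.k)
        n, oh, ow = cols.shape[:3]
        flat = cols.reshape(n * oh * ow, -1)
        if train:
            self._cols = flat
            self._xshape = x.shape
        out = flat @ self.W.reshape(-1, self.cout)
        return out.reshape(n, oh, ow, self.cout) + self.b

    def backward(self, dout):
        n, oh, ow, _ = dout.shape
        dflat = dout.reshape(n * oh * ow, self.cout)
        self.dW = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        self._cols = None
        if self.first:
            return None
        # input gradient as k*k shifted GEMM accumulations (avoids the
        # full-convolution im2col copy)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for a in range(self.k):
            for b in range(self.k):
                dx[:, a : a + oh, b : b + ow, :] += (
                    dflat @ self.W[a, b].T
                ).reshape(n, oh, ow, self.cin)
        return dx

    def params(self):
        return [("W", True), ("b", False)]


class MaxPool2:
    """2x2 max pooling, stride 2 (trailing odd row/column dropped)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        wf = win.reshape(n, h2, w2, c, 4)
        if train:
            self._arg = wf.argmax(axis=-1)
            self._xshape = x.shape
        return wf.max(axis=-1)

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        dwf = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dwf, self._arg[..., None], dout[..., None], axis=-1)
        dwin = dwf.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = dwin.reshape(n, 2 * h2, 2 * w2, c)
        return dx

    def params(self):
        return []


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class Dense:
    def __init__(self, nin, nout, rng):
        self.W = _he_uniform(rng, (nin, nout), nin)
        self.b = np.zeros(nout, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", True), ("b", False)]


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# network


@dataclass
class NetworkSpec:
    """Architecture description; defaults reproduce the reference layout."""

    n_views: int = 3
    input_size: int = 65
    conv_channels: tuple[int, int, int] = (24, 48, 96)
    kernel: int = 5
    fc_units: int = 512
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_views not in (1, 3, 9):
            raise ValueError("n_views must be 1, 3 or 9")

    def branch_shape_trace(self) -> list[tuple[int, int, int]]:
        """Spatial/channel shapes after each conv/pool layer of one branch."""
        s = self.input_size
        trace = []
        for i, ch in enumerate(self.conv_channels):
            s = s - self.kernel + 1
            trace.append((s, s, ch))
            if i < len(self.conv_channels) - 1:
                s = s // 2
                trace.append((s, s, ch))
        return trace

    @property
    def concat_features(self) -> int:
        side, _, ch = self.branch_shape_trace()[-1]
        return self.n_views * side * side * ch


class MultiViewNet:
    """Per-view conv branches with unshared weights, concat, FC head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dropout_fc: float = 0.2):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2, c3 = spec.conv_channels
        k = spec.kernel
        self.branches = []
        for _ in range(spec.n_views):
            self.branches.append(
                [
                    Conv2D(1, c1, k, rng, first=True),
                    ReLU(),
                    MaxPool2(),
                    Conv2D(c1, c2, k, rng),
                    ReLU(),
                    MaxPool2(),
                    Conv2D(c2, c3, k, rng),
                    ReLU(),
                ]
            )
        self.fc = Dense(spec.concat_features, spec.fc_units, rng)
        self.fc_relu = ReLU()
        self.dropout = Dropout(dropout_fc, rng)
        self.out = Dense(spec.fc_units, spec.n_classes, rng)
        self.head = [self.fc, self.fc_relu, self.dropout, self.out]

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        for branch in self.branches:
            yield from branch
        yield from self.head

    def weighted_layers(self):
        for layer in self.layers():
            if layer.params():
                yield layer

    def param_count(self) -> int:
        return sum(
            getattr(lyr, name).size for lyr in self.weighted_layers() for name, _ in lyr.params()
        )

    def get_weights(self):
        return [
            getattr(lyr, name).copy()
            for lyr in self.weighted_layers()
            for name, _ in lyr.params()
        ]

    def set_weights(self, weights):
        i = 0
        for lyr in self.weighted_layers():
            for name, _ in lyr.params():
                setattr(lyr, name, weights[i].copy())
                i += 1

    # -- forward / backward ------------------------------------------------
    def forward(self, views: np.ndarray, train: bool = False) -> np.ndarray:
        """views: (N, n_views, size, size) -> logits (N, n_classes)."""
        views = np.asarray(views, dtype=np.float32)
        if views.ndim != 4 or views.shape[1] != self.spec.n_views:
            raise ValueError(
                f"expected (N, {self.spec.n_views}, {self.spec.input_size}, "
                f"{self.spec.input_size}) input, got {views.shape}"
            )
        feats = []
        self._branch_out_shape = None
        for i, branch in enumerate(self.branches):
            x = views[:, i, :, :, None]
            for layer in branch:
                x = layer.forward(x, train)
            self._branch_out_shape = x.shape
            feats.append(x.reshape(len(x), -1))
        x = np.concatenate(feats, axis=1)
        for layer in self.head:
            x = layer.forward(x, train)
        return x

    def forward_trace(self, views: np.ndarray) -> list[tuple[int, ...]]:
        """Shapes (H, W, C) after every branch layer, for one branch."""
        x = np.asarray(views, dtype=np.float32)[:, 0, :, :, None]
        shapes = []
        for layer in self.branches[0]:
            x = layer.forward(x, train=False)
            if not isinstance(layer, ReLU):
                shapes.append(tuple(x.shape[1:]))
        return shapes

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(np.float32)
        for layer in reversed(self.head):
            d = layer.backward(d)
        n = len(dlogits)
        per = self.spec.concat_features // self.spec.n_views
        for i, branch in enumerate(self.branches):
            db = d[:, i * per : (i + 1) * per].reshape(self._branch_out_shape)
            for layer in reversed(branch):
                db = layer.backward(db)

    def predict_proba(self, views: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(views), batch_size):
            out.append(softmax(self.forward(views[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))


def build_network(spec: NetworkSpec, seed: int = 0, dropout_fc: float = 0.2) -> MultiViewNet:
    """Instantiate the multi-view network with seeded He-uniform weights."""
    return MultiViewNet(spec, seed=seed, dropout_fc=dropout_fc)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    nesterov_momentum: float = 0.9
    l2_lambda: float = 0.0005
    dropout_fc: float = 0.2
    batch_size: int = 32
    minibatches_per_epoch: int = 200
    max_epochs: int = 200
    early_stop_patience_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_fc < 1:
            raise ValueError("dropout_fc must be in [0, 1)")
        for name in (
            "learning_rate",
            "batch_size",
            "minibatches_per_epoch",
            "max_epochs",
            "early_stop_patience_epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CnnDataset:
    """Stacked multi-view patches with binary labels (1 node / 0 non-node)."""

    views: np.ndarray  # (M, n_views, 65, 65) float32
    labels: np.ndarray  # (M,) int

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.views) != len(self.labels):
            raise ValueError("views and labels disagree on length")

    @classmethod
    def from_patchsets(cls, patchsets: list[PatchSet]) -> "CnnDataset":
        if any(ps.label is None for ps in patchsets):
            raise ValueError("all patch sets must be labelled")
        return cls(
            np.stack([ps.patches for ps in patchsets]),
            np.array([ps.label for ps in patchsets]),
        )


class _SGDNesterov:
    def __init__(self, model: MultiViewNet, cfg: TrainConfig):
        self.model = model
        self.lr = cfg.learning_rate
        self.mu = cfg.nesterov_momentum
        self.l2 = cfg.l2_lambda
        self.vel = [
            np.zeros_like(getattr(lyr, name))
            for lyr in model.weighted_layers()
            for name, _ in lyr.params()
        ]

    def step(self) -> None:
        i = 0
        for lyr in self.model.weighted_layers():
            for name, is_weight in lyr.params():
                p = getattr(lyr, name)
                g = getattr(lyr, "d" + name)
                if g.dtype != np.float32:
                    g = g.astype(np.float32)
                if is_weight and self.l2 > 0:
                    g = g + (2.0 * self.l2) * p
                v = self.vel[i]
                v *= self.mu
                v -= self.lr * g
                # Nesterov look-ahead update, in place
                p += self.mu * v
                p -= self.lr * g
                i += 1


def _loss_and_grad(model: MultiViewNet, views, labels, l2: float):
    logits = model.forward(views, train=True)
    p = softmax(logits)
    n = len(labels)
    ce = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    reg = l2 * sum(
        float((getattr(lyr, name) ** 2).sum())
        for lyr in model.weighted_layers()
        for name, is_w in lyr.params()
        if is_w
    )
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return ce + reg, dlogits


def sample_balanced_batch(labels: np.ndarray, batch_size: int, rng) -> np.ndarray:
    """Indices of a class-balanced mini-batch, sampled with replacement."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance mini-batches")
    half = batch_size // 2
    return np.concatenate([rng.choice(pos, half), rng.choice(neg, batch_size - half)])


def validation_accuracy(model: MultiViewNet, dataset: CnnDataset) -> float:
    prob = model.predict_proba(dataset.views)[:, 1]
    return float(((prob >= 0.5).astype(int) == dataset.labels).mean())


def train_network(
    model: MultiViewNet,
    train_set: CnnDataset,
    val_set: CnnDataset,
    cfg: TrainConfig,
) -> tuple[MultiViewNet, pd.DataFrame]:
    """SGD training with balanced mini-batches and early stopping.

    Each mini-batch draws batch_size/2 positives and negatives with
    replacement from the training pool.  Validation accuracy is computed on
    the full validation set at every epoch end; training stops when it has
    not improved for more than the patience, and the weights of the best
    epoch are restored.
    """
    for name, ds in (("train", train_set), ("validation", val_set)):
        if len(np.unique(ds.labels)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = _SGDNesterov(model, cfg)
    best_acc, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for _ in range(cfg.minibatches_per_epoch):
            idx = sample_balanced_batch(train_set.labels, cfg.batch_size, rng)
            loss, dlogits = _loss_and_grad(
                model, train_set.views[idx], train_set.labels[idx], cfg.l2_lambda
            )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = validation_accuracy(model, val_set)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
        if val_acc > best_acc:
            best_acc, best_epoch, best_weights = val_acc, epoch, model.get_weights()
        if epoch - best_epoch > cfg.early_stop_patience_epochs:
            break
    model.set_weights(best_weights)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# training-set assembly and scoring


@dataclass
class CnnTrainingSet:
    """Candidate positions labelled for the false-positive-reduction stage."""

    positives: list[Candidate] = field(default_factory=list)
    negatives: list[Candidate] = field(default_factory=list)

    def labeled(self) -> list[tuple[Candidate, int]]:
        return [(c, 1) for c in self.positives] + [(c, 0) for c in self.negatives]


def build_cnn_training_set(
    candidates: list[Candidate],
    annotation: AnnotationMap,
    fp_subsample: float | int = 1.0,
    rng_seed: int = 0,
) -> CnnTrainingSet:
    """Assemble stage-2 training positions from matched stage-1 output.

    Positives are every true-positive candidate (the representative per
    detected node) plus, for every annotated node the first stage missed, a
    pseudo-candidate at the node's center of gravity -- so the CNN trains on
    all nodes, not only those stage 1 found.  Negatives are a seeded random
    subset of the false-positive candidates (a fraction if fp_subsample <= 1,
    else an absolute count).
    """
    rng = np.random.default_rng(rng_seed)
    per_node: dict[int, Candidate] = {}
    fps: list[Candidate] = []
    for cand in candidates:
        if cand.node_label is None:
            fps.append(cand)
        else:
            cur = per_node.get(cand.node_label)
            if cur is None or cand.likelihood > cur.likelihood:
                per_node[cand.node_label] = cand
    positives = [per_node[k] for k in sorted(per_node)]
    for prop in node_properties(annotation):
        if prop.label not in per_node:
            idx = np.round(prop.center_mm / annotation.spacing_mm - 0.5).astype(int)
            idx = np.clip(idx, 0, np.array(annotation.shape) - 1)
            positives.append(
                Candidate(
                    voxel_index=tuple(int(v) for v in idx),
                    position_mm=prop.center_mm,
                    likelihood=0.0,
                    node_label=prop.label,
                )
            )
    if not positives:
        raise ValueError("no positive samples: no nodes annotated")
    if fp_subsample <= 1.0:
        n_neg = int(round(fp_subsample * len(fps)))
    else:
        n_neg = min(int(fp_subsample), len(fps))
    sel = rng.choice(len(fps), size=n_neg, replace=False) if n_neg < len(fps) else np.arange(len(fps))
    negatives = [fps[i] for i in sorted(sel)]
    return CnnTrainingSet(positives=positives, negatives=negatives)


def score_candidates(
    model: MultiViewNet, patchsets: list[PatchSet], batch_size: int = 64
) -> np.ndarray:
    """Softmax node-class probability per candidate; fills cnn_probability."""
    if not patchsets:
        return np.zeros(0)
    views = np.stack([ps.patches for ps in patchsets])
    if views.shape[1] != model.spec.n_views:
        raise ValueError(
            f"patch sets have {views.shape[1]} views, model expects {model.spec.n_views}"
        )
    prob = model.predict_proba(views, batch_size=batch_size)[:, 1]
    for ps, p in zip(patchsets, prob):
        ps.candidate.cnn_probability = float(p)
    return prob
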