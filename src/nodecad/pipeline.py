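"""End-to-end orchestration: phantoms -> stage 1 -> multi-view CNN -> FROC.

The experiment layout mirrors the two-stage detection study: a boosted
voxel classifier proposes candidates, a multi-view CNN rescores them, and
both systems are evaluated on pooled test folds of a patient-level 5-fold
cross-validation, compared by bootstrapped partial AUC of the FROC curve.
Every stage is seeded through :func:`nodecad.config.module_seed` so a
single global seed reproduces the whole experiment.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evalstats, mvcnn, stage1 as s1
from .config import PipelineConfig, module_seed
from .features import FeatureStack, compute_default_features, normalize_intensity
from .multiview import make_view_set
from .mvcnn import CnnDataset, NetworkSpec, TrainConfig
from .phantom import Phantom, PhantomConfig, generate_phantom
from .volume import ImageVolume, load_annotation, load_volume


@dataclass
class PhantomData:
    """One phantom with everything the pipeline derives from it."""

    patient_id: int
    phantom: Phantom
    features: FeatureStack = None
    norm_t1: ImageVolume = None
    n_nodes: int = 0

    def prepare(self, cfg: PipelineConfig) -> "PhantomData":
        if self.features is None:
            self.features = compute_default_features(
                self.phantom.t1_like,
                self.phantom.t2s_like,
                scales_mm=cfg.stage1.scales_mm,
            )
            self.norm_t1 = normalize_intensity(self.phantom.t1_like)
            self.n_nodes = len(self.phantom.annotation.node_labels())
        return self


def simulate_dataset(
    cfg: PipelineConfig, out_dir: str | None = None
) -> list[PhantomData]:
    """Generate the phantom cohort; optionally persist it with a manifest."""
    data = []
    for i in range(cfg.n_phantoms):
        pcfg = replace(cfg.phantom, seed=module_seed(cfg.seed, "phantom", i))
        data.append(PhantomData(patient_id=i, phantom=generate_phantom(pcfg)))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        entries = []
        for pd_ in data:
            prefix = os.path.join(out_dir, f"phantom_{pd_.patient_id:03d}")
            paths = pd_.phantom.save(prefix)
            entry = {"patient_id": pd_.patient_id, "paths": paths}
            entry["n_nodes"] = len(pd_.phantom.annotation.node_labels())
            entry["sha256"] = {
                key: _sha256(path) for key, path in paths.items()
            }
            entries.append(entry)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump({"n_phantoms": cfg.n_phantoms, "seed": cfg.seed,
                       "entries": entries}, fh, indent=1)
    return data


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def load_dataset(data_dir: str) -> list[PhantomData]:
    with open(os.path.join(data_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    data = []
    for entry in manifest["entries"]:
        t1 = load_volume(entry["paths"]["t1_like"])
        t2 = load_volume(entry["paths"]["t2s_like"])
        ann = load_annotation(entry["paths"]["annotation"])
        data.append(
            PhantomData(
                patient_id=entry["patient_id"],
                phantom=Phantom(t1, t2, ann, None),
            )
        )
    return data


def train_stage1(
    data: list[PhantomData], cfg: PipelineConfig, seed_extra: int = 0
) -> s1.BoostModel:
    """Fit the GentleBoost voxel classifier on pooled balanced voxel rows."""
    per_cap = max(50, cfg.stage1.max_voxels_per_class // max(len(data), 1))
    Xs, ys = [], []
    for pd_ in data:
        X, y = s1.build_voxel_training_set(
            pd_.features,
            pd_.phantom.annotation,
            rng_seed=module_seed(cfg.seed, "voxel_training", seed_extra * 1000 + pd_.patient_id),
            max_per_class=per_cap,
        )
        Xs.append(X)
        ys.append(y)
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    return s1.fit_gentleboost(
        X, y, n_rounds=cfg.stage1.n_rounds, feature_names=data[0].features.names
    )


def detect_on(
    model: s1.BoostModel, pd_: PhantomData, cfg: PipelineConfig
) -> list[s1.Candidate]:
    """Likelihood map -> spherical-window maxima -> matched candidates."""
    lik = s1.predict_likelihood(model, pd_.features)
    cands = s1.detect_candidates(
        lik,
        window_diameter_mm=cfg.stage1.window_diameter_mm,
        floor=cfg.stage1.floor,
    )
    return evalstats.match_candidates(cands, pd_.phantom.annotation)


def _patchsets_for(
    pd_: PhantomData, labeled: list[tuple[s1.Candidate, int]], n_views: int
):
    return [
        make_view_set(pd_.norm_t1, cand, n_views, label=lab) for cand, lab in labeled
    ]


@dataclass
class ExperimentResult:
    systems: list[str]
    patients: dict[str, list[evalstats.PatientResult]]
    curves: dict[str, evalstats.FROCCurve]
    comparison: evalstats.ComparisonResult
    histories: list[pd.DataFrame] = field(default_factory=list)
    fold_split: evalstats.FoldSplit = None

    def pauc(self, system: str) -> float:
        return self.comparison.pauc_per_system[system][0]

    def fp_per_image_at(self, system: str, sensitivity: float) -> float:
        return self.curves[system].fp_per_image_at_sensitivity(sensitivity)


def run_experiment(
    cfg: PipelineConfig, views_list: tuple[int, ...] = (3,)
) -> ExperimentResult:
    """The full cross-validated two-stage experiment on a phantom cohort.

    Per cross-validation run: stage 1 is trained on the three training
    folds; its candidates on train/validation folds form the CNN training
    and validation sets (all nodes -- found or missed -- as positives, a
    seeded subset of false positives as negatives); the trained CNN then
    rescores the held-out test fold.  Test-fold results pooled over the
    five runs yield one FROC per system; systems share candidates, so the
    bootstrap comparison is paired.
    """
    data = [pd_.prepare(cfg) for pd_ in simulate_dataset(cfg)]
    k = cfg.eval.k_folds
    folds = evalstats.stratified_patient_folds(
        {pd_.patient_id: pd_.n_nodes for pd_ in data},
        k=k,
        seed=module_seed(cfg.seed, "folds"),
    )
    by_id = {pd_.patient_id: pd_ for pd_ in data}
    systems = ["stage1"] + [f"{v}view" for v in views_list]
    pooled: dict[str, list] = {name: [None] * len(data) for name in systems}
    histories = []
    for run in range(k):
        train_f, val_f, test_f = evalstats.cv_run_roles(run, k)
        train_ids = [p for p, f in folds.fold_assignment.items() if f in train_f]
        val_ids = folds.members(val_f)
        test_ids = folds.members(test_f)
        model = train_stage1([by_id[i] for i in train_ids], cfg, seed_extra=run)
        cands = {i: detect_on(model, by_id[i], cfg) for i in by_id}

        def _labeled(ids, subsample):
            out = []
            for i in ids:
                ts = mvcnn.build_cnn_training_set(
                    cands[i],
                    by_id[i].phantom.annotation,
                    fp_subsample=subsample,
                    rng_seed=module_seed(cfg.seed, "cnn_training", run * 1000 + i),
                )
                out.extend((c, lab, i) for c, lab in ts.labeled())
            return out

        for v in views_list:
            train_rows = _labeled(train_ids, cfg.fp_subsample)
            val_rows = _labeled(val_ids, 1.0)
            spec = NetworkSpec(n_views=v)
            net = mvcnn.build_network(
                spec,
                seed=module_seed(cfg.seed, "cnn_init", run * 10 + v),
                dropout_fc=cfg.train.dropout_fc,
            )
            tcfg = replace(cfg.train, seed=module_seed(cfg.seed, "cnn_training", run * 10 + v))
            train_ds = CnnDataset.from_patchsets(
                [ps for c, lab, i in train_rows for ps in [_mk(by_id[i], c, v, lab)]]
            )
            val_ds = CnnDataset.from_patchsets(
                [ps for c, lab, i in val_rows for ps in [_mk(by_id[i], c, v, lab)]]
            )
            net, hist = mvcnn.train_network(net, train_ds, val_ds, tcfg)
            histories.append(hist)
            for i in test_ids:
                if cands[i]:
                    patchsets = [make_view_set(by_id[i].norm_t1, c, v) for c in cands[i]]
                    mvcnn.score_candidates(net, patchsets)
                pooled[f"{v}view"][i] = evalstats.PatientResult.from_candidates(
                    cands[i], by_id[i].n_nodes, system="cnn"
                )
        for i in test_ids:
            pooled["stage1"][i] = evalstats.PatientResult.from_candidates(
                cands[i], by_id[i].n_nodes, system="stage1"
            )
    comparison = evalstats.compare_all_systems(
        pooled,
        n_boot=cfg.eval.n_boot,
        fp_range=(cfg.eval.fp_lo, cfg.eval.fp_hi),
        seed=module_seed(cfg.seed, "bootstrap"),
    )
    curves = {name: evalstats.froc_curve(pooled[name]) for name in systems}
    return ExperimentResult(
        systems=systems,
        patients=pooled,
        curves=curves,
        comparison=comparison,
        histories=histories,
        fold_split=folds,
    )


def _mk(pd_: PhantomData, cand, n_views, label):
    return make_view_set(pd_.norm_t1, cand, n_views, label=label)


def reduced_scale_config(seed: int = 0, n_phantoms: int = 20) -> PipelineConfig:
    """Desk-scale study conditions: the reference operating values for every
    method parameter, with the cohort, grids, and CNN iteration counts sized
    for a single CPU (see the methods note)."""
    return PipelineConfig(
        phantom=PhantomConfig(),
        n_phantoms=n_phantoms,
        train=TrainConfig(
            minibatches_per_epoch=20,
            max_epochs=3,
            early_stop_patience_epochs=20,
        ),
        seed=seed,
    )
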