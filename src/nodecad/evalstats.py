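"""FROC evaluation with bootstrapped confidence bands and system comparison.

Candidates are matched to the reference annotation by segmentation
membership: a candidate whose voxel lies inside a node's label mask is a
hit for that node, the highest-scoring hit represents the node, surplus
hits are ignored (neither true nor false positive), and candidates outside
every node are false positives.  The FROC curve plots the fraction of
annotated nodes detected against false positives per node (and per image)
as the score threshold varies.  The figure of merit is the partial area
under the FROC curve between 0.25 and 32 false positives per node
(trapezoidal, linear FP axis, sensitivity as a fraction; maximum 31.75).
Uncertainty comes from resampling patients with replacement; systems are
compared with a paired one-sided bootstrap test on the pAUC, Bonferroni
corrected for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stage1 import Candidate
from .volume import AnnotationMap

PAUC_FP_RANGE = (0.25, 32.0)


# ---------------------------------------------------------------------------
# matching


def match_candidates(
    candidates: list[Candidate], annotation: AnnotationMap
) -> list[Candidate]:
    """Set node_label on every candidate whose voxel lies inside a node."""
    shape = annotation.shape
    for cand in candidates:
        idx = cand.voxel_index
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            raise ValueError(f"candidate index {idx} outside grid {shape}")
        lab = int(annotation.labels[idx])
        cand.node_label = lab if lab > 0 else None
    return candidates


@dataclass
class PatientResult:
    """Matched candidates and node count for one image/patient."""

    node_scores: np.ndarray  # best candidate score per detected node
    fp_scores: np.ndarray  # scores of false-positive candidates
    n_nodes: int  # annotated nodes in this image

    @classmethod
    def from_candidates(
        cls, candidates: list[Candidate], n_nodes: int, system: str = "stage1"
    ) -> "PatientResult":
        per_node: dict[int, float] = {}
        fps = []
        for cand in candidates:
            score = cand.score(system)
            if cand.node_label is None:
                fps.append(score)
            else:
                cur = per_node.get(cand.node_label, -np.inf)
                per_node[cand.node_label] = max(cur, score)
        return cls(
            node_scores=np.asarray(sorted(per_node.values()), dtype=float),
            fp_scores=np.asarray(sorted(fps), dtype=float),
            n_nodes=n_nodes,
        )


# ---------------------------------------------------------------------------
# FROC


@dataclass
class FROCCurve:
    thresholds: np.ndarray  # descending score cutoffs
    sensitivity: np.ndarray
    fp_per_node: np.ndarray
    fp_per_image: np.ndarray
    n_nodes: int
    n_images: int
    band_fp_per_node: np.ndarray | None = field(default=None)
    band_lo: np.ndarray | None = field(default=None)
    band_hi: np.ndarray | None = field(default=None)

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "fp_per_node": self.fp_per_node,
                "fp_per_image": self.fp_per_image,
            }
        )
        df.to_csv(path, index=False)

    def fp_per_image_at_sensitivity(self, target: float) -> float:
        """Smallest FP/image among operating points with sensitivity >= target."""
        ok = self.sensitivity >= target
        if not ok.any():
            return float("inf")
        return float(self.fp_per_image[ok].min())


def froc_curve(patients: list[PatientResult]) -> FROCCurve:
    """Pooled FROC over patients, one operating point per distinct score."""
    n_nodes = sum(p.n_nodes for p in patients)
    n_images = len(patients)
    if n_nodes < 1:
        raise ValueError("FROC requires at least one annotated node")
    node_scores = np.concatenate([p.node_scores for p in patients]) if patients else np.zeros(0)
    fp_scores = np.concatenate([p.fp_scores for p in patients]) if patients else np.zeros(0)
    all_scores = np.concatenate([node_scores, fp_scores])
    if not np.all(np.isfinite(all_scores)):
        raise ValueError("candidate scores must be finite")
    thresholds = np.unique(all_scores)[::-1]
    if len(thresholds) == 0:
        thresholds = np.array([0.0])
    node_sorted = np.sort(node_scores)
    fp_sorted = np.sort(fp_scores)
    # counts with score >= t via searchsorted on the ascending arrays
    n_det = len(node_sorted) - np.searchsorted(node_sorted, thresholds, side="left")
    n_fp = len(fp_sorted) - np.searchsorted(fp_sorted, thresholds, side="left")
    return FROCCurve(
        thresholds=thresholds,
        sensitivity=n_det / n_nodes,
        fp_per_node=n_fp / n_nodes,
        fp_per_image=n_fp / n_images,
        n_nodes=n_nodes,
        n_images=n_images,
    )


def _polyline(curve: FROCCurve) -> tuple[np.ndarray, np.ndarray]:
    """Operating points as an ordered FP-vs-sensitivity polyline.

    Ordered by (FP, sensitivity); equal-FP runs are vertical jumps
    (thresholds that add node detections without new false positives) and
    contribute no area.  The implicit everything-rejected point (0, 0) is
    prepended when absent.
    """
    x, y = curve.fp_per_node, curve.sensitivity
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    if len(x) == 0 or x[0] > 0:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[0.0], y])
    return x, y


def _sens_at_fp(curve: FROCCurve, fp_abscissae: np.ndarray) -> np.ndarray:
    """Piecewise-linear sensitivity vs FP/node, step-extended beyond the end."""
    xs, ys = _polyline(curve)
    return np.interp(fp_abscissae, xs, ys, right=ys[-1])


def partial_auc(
    curve: FROCCurve, fp_lo: float = PAUC_FP_RANGE[0], fp_hi: float = PAUC_FP_RANGE[1]
) -> float:
    """Trapezoidal pAUC of sensitivity vs FP/node on a linear axis.

    The curve is linearly interpolated at the bounds and step-extended with
    its last sensitivity beyond its last operating point; the maximum
    possible value is fp_hi - fp_lo (31.75 for the default range).
    """
    if fp_lo >= fp_hi:
        raise ValueError("fp_lo must be < fp_hi")
    xs, ys = _polyline(curve)
    inside = (xs >= fp_lo) & (xs <= fp_hi)
    y_lo = np.interp(fp_lo, xs, ys, right=ys[-1])
    y_hi = np.interp(fp_hi, xs, ys, right=ys[-1])
    # keep duplicate-x jump points: vertical segments carry no area but fix
    # which sensitivity the outgoing segment starts from
    X = np.concatenate([[fp_lo], xs[inside], [fp_hi]])
    Y = np.concatenate([[y_lo], ys[inside], [y_hi]])
    return float(np.trapezoid(Y, X))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    pauc: float  # point estimate
    pauc_ci: tuple[float, float]
    pauc_replicates: np.ndarray
    band_fp_per_node: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    seed: int
    n_boot: int


def bootstrap_froc(
    patients: list[PatientResult],
    n_boot: int = 1000,
    fp_range: tuple[float, float] = PAUC_FP_RANGE,
    seed: int = 0,
    band_abscissae: np.ndarray | None = None,
) -> BootstrapResult:
    """Patient-level bootstrap of the FROC curve and its pAUC.

    Patients are resampled with replacement; each replicate recomputes the
    pooled curve and pAUC.  Bands are percentile 2.5/97.5 of sensitivity at
    fixed FP/node abscissae.  Deterministic per seed.
    """
    if len(patients) < 2:
        raise ValueError("bootstrap needs at least two patients")
    rng = np.random.default_rng(seed)
    if band_abscissae is None:
        band_abscissae = np.geomspace(fp_range[0], fp_range[1], 25)
    point_curve = froc_curve(patients)
    point_pauc = partial_auc(point_curve, *fp_range)
    paucs = np.empty(n_boot)
    bands = np.empty((n_boot, len(band_abscissae)))
    n = len(patients)
    for b in range(n_boot):
        sel = rng.integers(0, n, size=n)
        rep = [patients[i] for i in sel]
        curve = froc_curve(rep)
        paucs[b] = partial_auc(curve, *fp_range)
        bands[b] = _sens_at_fp(curve, band_abscissae)
    lo, hi = np.percentile(paucs, [2.5, 97.5])
    return BootstrapResult(
        pauc=point_pauc,
        pauc_ci=(float(lo), float(hi)),
        pauc_replicates=paucs,
        band_fp_per_node=band_abscissae,
        band_lo=np.percentile(bands, 2.5, axis=0),
        band_hi=np.percentile(bands, 97.5, axis=0),
        seed=seed,
        n_boot=n_boot,
    )


def bootstrap_systems(
    per_system_patients: dict[str, list[PatientResult]],
    n_boot: int = 1000,
    fp_range: tuple[float, float] = PAUC_FP_RANGE,
    seed: int = 0,
) -> dict[str, BootstrapResult]:
    """Bootstrap several systems on the SAME resampled patients per replicate.

    Pairing across systems is what makes compare_systems a paired test, so
    all systems must cover the same patient list (same length and order).
    """
    lengths = {len(v) for v in per_system_patients.values()}
    if len(lengths) != 1:
        raise ValueError("all systems must cover the same patients")
    (n,) = lengths
    if n < 2:
        raise ValueError("bootstrap needs at least two patients")
    rng = np.random.default_rng(seed)
    names = list(per_system_patients)
    abscissae = np.geomspace(fp_range[0], fp_range[1], 25)
    paucs = {k: np.empty(n_boot) for k in names}
    bands = {k: np.empty((n_boot, len(abscissae))) for k in names}
    for b in range(n_boot):
        sel = rng.integers(0, n, size=n)
        for k in names:
            rep = [per_system_patients[k][i] for i in sel]
            curve = froc_curve(rep)
            paucs[k][b] = partial_auc(curve, *fp_range)
            bands[k][b] = _sens_at_fp(curve, abscissae)
    out = {}
    for k in names:
        curve = froc_curve(per_system_patients[k])
        lo, hi = np.percentile(paucs[k], [2.5, 97.5])
        out[k] = BootstrapResult(
            pauc=partial_auc(curve, *fp_range),
            pauc_ci=(float(lo), float(hi)),
            pauc_replicates=paucs[k],
            band_fp_per_node=abscissae,
            band_lo=np.percentile(bands[k], 2.5, axis=0),
            band_hi=np.percentile(bands[k], 97.5, axis=0),
            seed=seed,
            n_boot=n_boot,
        )
    return out


def compare_systems(
    pauc_reps_a: np.ndarray, pauc_reps_b: np.ndarray, n_comparisons: int = 1
) -> tuple[float, float]:
    """Paired one-sided bootstrap test of H1: system B > system A.

    raw p is the fraction of paired replicates where B does not beat A,
    with ties half-weighted and the (count+1)/(n+1) small-sample
    correction; the adjusted p applies the Bonferroni factor, capped at 1.
    Returns (raw_p, adjusted_p).
    """
    a = np.asarray(pauc_reps_a, dtype=float)
    b = np.asarray(pauc_reps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate arrays must be paired (equal length)")
    n = len(a)
    worse = np.count_nonzero(b < a) + 0.5 * np.count_nonzero(b == a)
    raw = (worse + 1.0) / (n + 1.0)
    return float(raw), float(min(1.0, raw * n_comparisons))


@dataclass
class ComparisonResult:
    pauc_per_system: dict[str, tuple[float, tuple[float, float]]]
    p_values: dict[tuple[str, str], float]  # (A, B): adjusted one-sided p for B > A
    raw_p_values: dict[tuple[str, str], float]
    n_bootstrap: int
    fp_range: tuple[float, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), p in self.p_values.items():
            rows.append({"system_a": a, "system_b": b, "p_adjusted": p,
                         "p_raw": self.raw_p_values[(a, b)]})
        return pd.DataFrame(rows)


def compare_all_systems(
    per_system_patients: dict[str, list[PatientResult]],
    n_boot: int = 1000,
    fp_range: tuple[float, float] = PAUC_FP_RANGE,
    seed: int = 0,
) -> ComparisonResult:
    """Bootstrap every system jointly and test all ordered improvements.

    For every pair the later-listed system is tested against the earlier
    one (H1: later > earlier), Bonferroni-corrected by the number of pairs.
    """
    boot = bootstrap_systems(per_system_patients, n_boot, fp_range, seed)
    names = list(per_system_patients)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    p_values, raw_p = {}, {}
    for a, b in pairs:
        raw, adj = compare_systems(
            boot[a].pauc_replicates, boot[b].pauc_replicates, n_comparisons=m
        )
        p_values[(a, b)] = adj
        raw_p[(a, b)] = raw
    return ComparisonResult(
        pauc_per_system={k: (boot[k].pauc, boot[k].pauc_ci) for k in names},
        p_values=p_values,
        raw_p_values=raw_p,
        n_bootstrap=n_boot,
        fp_range=fp_range,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-validation folds


@dataclass
class FoldSplit:
    fold_assignment: dict[object, int]
    node_counts: list[int]

    def members(self, fold: int) -> list:
        return [p for p, f in self.fold_assignment.items() if f == fold]


def stratified_patient_folds(
    patient_node_counts: dict[object, int], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Patient-level folds balanced on annotated-node counts.

    Greedy: patients sorted by node count descending (ties shuffled by
    seed) are assigned to the currently lightest fold, so each fold ends up
    with (near-)equal numbers of nodes.
    """
    patients = list(patient_node_counts)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))  # random tie-break
    patients = [patients[i] for i in order]
    patients.sort(key=lambda p: -patient_node_counts[p])
    counts = [0] * k
    assignment = {}
    for p in patients:
        fold = int(np.argmin(counts))
        assignment[p] = fold
        counts[fold] += patient_node_counts[p]
    return FoldSplit(fold_assignment=assignment, node_counts=counts)


def cv_run_roles(run: int, k: int = 5) -> tuple[list[int], int, int]:
    """(train_folds, val_fold, test_fold) for one cross-validation run."""
    test = run % k
    val = (run + 1) % k
    train = [f for f in range(k) if f not in (test, val)]
    return train, val, test


# ---------------------------------------------------------------------------
# supplementary raw-FROC reader


def read_froc_csv(path: str) -> FROCCurve:
    """Read a raw FROC-curve table as published in supplementary datasets.

    Auto-detects the delimiter.  Column resolution: an FP-rate column named
    like fp/fppi/fp_per_node/x and a sensitivity column named like
    sensitivity/tpr/y; otherwise the first two numeric columns are taken as
    (fp_per_node, sensitivity).  Sensitivities given in percent are
    rescaled to fractions.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    fp_col = next(
        (cols[k] for k in cols if k in ("fp_per_node", "fppn", "fp", "fppi", "x")
         or "false" in k or k.startswith("fp")),
        None,
    )
    sens_col = next(
        (cols[k] for k in cols if "sens" in k or k in ("tpr", "y")), None
    )
    numeric = df.select_dtypes("number").columns
    if fp_col is None or sens_col is None:
        if len(numeric) < 2:
            raise ValueError("could not identify FP and sensitivity columns")
        fp_col, sens_col = numeric[0], numeric[1]
    fp = df[fp_col].to_numpy(dtype=float)
    sens = df[sens_col].to_numpy(dtype=float)
    if np.nanmax(sens) > 1.5:  # given in percent
        sens = sens / 100.0
    order = np.argsort(fp, kind="stable")
    fp, sens = fp[order], sens[order]
    return FROCCurve(
        thresholds=np.arange(len(fp), 0, -1, dtype=float),
        sensitivity=sens,
        fp_per_node=fp,
        fp_per_image=np.full_like(fp, np.nan),
        n_nodes=0,
        n_images=0,
    )
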