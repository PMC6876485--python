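import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodecad.evalstats import (
    FROCCurve,
    PatientResult,
    bootstrap_froc,
    bootstrap_systems,
    compare_all_systems,
    compare_systems,
    cv_run_roles,
    froc_curve,
    match_candidates,
    partial_auc,
    read_froc_csv,
    stratified_patient_folds,
)
from nodecad.stage1 import Candidate
from nodecad.volume import AnnotationMap

# ---------------------------------------------------------------------------
# oracles


def brute_force_froc(node_scores, fp_scores, n_nodes, n_images, thresholds):
    """Explicit per-threshold recount of detected nodes and false positives."""
    sens, fppn, fppi = [], [], []
    for t in thresholds:
        n_det = sum(1 for s in node_scores if s >= t)
        n_fp = sum(1 for s in fp_scores if s >= t)
        sens.append(n_det / n_nodes)
        fppn.append(n_fp / n_nodes)
        fppi.append(n_fp / n_images)
    return np.array(sens), np.array(fppn), np.array(fppi)


def brute_force_pauc(fp, sens, lo, hi):
    """Trapezoidal integral on the piecewise-linear (fp, sens) curve with
    step extension beyond the last point, evaluated with numpy.trapezoid on
    a dense grid plus breakpoints; epsilon offsets around each breakpoint
    keep vertical jumps (duplicate fp values) exact."""
    fp = np.concatenate([[0.0], fp, [max(hi, fp[-1]) + 1]])
    sens = np.concatenate([[0.0], sens, [sens[-1]]])
    eps = 1e-9
    breakpoints = np.concatenate([fp, fp - eps, fp + eps])
    xs = np.concatenate([np.linspace(lo, hi, 4001), breakpoints])
    xs = np.unique(np.clip(xs, lo, hi))
    ys = np.interp(xs, fp, sens)
    return np.trapezoid(ys, xs)


def _patient(node_scores, fp_scores, n_nodes):
    return PatientResult(
        node_scores=np.asarray(node_scores, dtype=float),
        fp_scores=np.asarray(fp_scores, dtype=float),
        n_nodes=n_nodes,
    )


# ---------------------------------------------------------------------------
# matching


class TestMatchCandidates:
    def _annotation(self):
        labels = np.zeros((16, 16, 16), dtype=np.int32)
        labels[4:7, 4:7, 4:7] = 1
        return AnnotationMap(labels, 0.8)

    def _cand(self, idx, score):
        return Candidate(idx, (np.array(idx) + 0.5) * 0.8, score)

    def test_inside_and_outside(self):
        ann = self._annotation()
        cands = match_candidates(
            [self._cand((5, 5, 5), 0.9), self._cand((12, 12, 12), 0.8)], ann
        )
        assert cands[0].node_label == 1
        assert cands[1].node_label is None

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            match_candidates([self._cand((20, 5, 5), 0.9)], self._annotation())

    def test_multiple_hits_best_represents_node(self):
        ann = self._annotation()
        cands = match_candidates(
            [self._cand((5, 5, 5), 0.9), self._cand((5, 5, 6), 0.4),
             self._cand((1, 1, 1), 0.7)],
            ann,
        )
        res = PatientResult.from_candidates(cands, n_nodes=1)
        # the node is represented once, by its best score; FP count unchanged
        np.testing.assert_allclose(res.node_scores, [0.9])
        np.testing.assert_allclose(res.fp_scores, [0.7])
        curve = froc_curve([res])
        # the node counts as detected at every threshold at or below 0.9
        sens_at = dict(zip(curve.thresholds, curve.sensitivity))
        assert sens_at[0.9] == 1.0 and sens_at[0.7] == 1.0
        # the surplus hit introduces no operating point of its own
        assert 0.4 not in curve.thresholds


# ---------------------------------------------------------------------------
# FROC + pAUC


class TestFROC:
    def test_perfect_detector(self):
        res = _patient([0.9, 0.95], [], 2)
        curve = froc_curve([res])
        assert curve.sensitivity[-1] == 1.0
        assert curve.fp_per_image[np.argmax(curve.sensitivity == 1.0)] == 0.0

    def test_hand_enumerated_operating_points(self):
        # 2 nodes, 1 detected at 0.8; FPs at 0.9, 0.7, 0.6; 1 image
        res = _patient([0.8], [0.9, 0.7, 0.6], 2)
        curve = froc_curve([res])

        def at(t):
            n_det = (res.node_scores >= t).sum()
            n_fp = (res.fp_scores >= t).sum()
            return n_det / 2, n_fp / 1

        assert at(0.75) == (0.5, 1.0)
        assert at(0.5) == (0.5, 3.0)
        # the computed curve agrees with the recount at its own thresholds
        for t, s, f in zip(curve.thresholds, curve.sensitivity, curve.fp_per_image):
            assert (s, f) == at(t)

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            froc_curve([_patient([], [0.5], 0)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sensitivity_monotone_as_threshold_decreases(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(1, 6))
        res = _patient(
            rng.random(rng.integers(0, n_nodes + 1)),
            rng.choice(rng.random(6), size=rng.integers(0, 8)),
            n_nodes,
        )
        curve = froc_curve([res])
        assert np.all(np.diff(curve.sensitivity) >= 0)  # thresholds descend
        assert np.all((curve.sensitivity >= 0) & (curve.sensitivity <= 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        patients = []
        for _ in range(3):
            n_nodes = int(rng.integers(1, 5))
            n_det = int(rng.integers(0, n_nodes + 1))
            patients.append(
                _patient(rng.random(n_det), rng.random(rng.integers(0, 12)), n_nodes)
            )
        curve = froc_curve(patients)
        node_scores = np.concatenate([p.node_scores for p in patients])
        fp_scores = np.concatenate([p.fp_scores for p in patients])
        sens, fppn, fppi = brute_force_froc(
            node_scores, fp_scores, curve.n_nodes, curve.n_images, curve.thresholds
        )
        np.testing.assert_allclose(curve.sensitivity, sens)
        np.testing.assert_allclose(curve.fp_per_node, fppn)
        np.testing.assert_allclose(curve.fp_per_image, fppi)


class TestPartialAUC:
    def _curve(self, fp, sens):
        fp = np.asarray(fp, dtype=float)
        sens = np.asarray(sens, dtype=float)
        return FROCCurve(
            thresholds=np.arange(len(fp), 0, -1, dtype=float),
            sensitivity=sens,
            fp_per_node=fp,
            fp_per_image=fp,
            n_nodes=1,
            n_images=1,
        )

    def test_perfect_detector_attains_maximum(self):
        assert partial_auc(self._curve([0.0], [1.0])) == pytest.approx(31.75)

    def test_constant_half_sensitivity(self):
        curve = self._curve([0.0, 40.0], [0.5, 0.5])
        assert partial_auc(curve) == pytest.approx(15.875)

    def test_piecewise_curve_trapezoid(self):
        curve = self._curve([0.25, 16.0, 32.0], [0.6, 0.8, 0.9])
        expected = 0.5 * (0.6 + 0.8) * 15.75 + 0.5 * (0.8 + 0.9) * 16.0
        assert expected == pytest.approx(24.625)
        assert partial_auc(curve) == pytest.approx(expected)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            partial_auc(self._curve([0.0], [1.0]), fp_lo=4, fp_hi=4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_numeric_integration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        fp = np.sort(rng.uniform(0, 50, size=n))
        sens = np.sort(rng.uniform(0, 1, size=n))
        curve = self._curve(fp, sens)
        expected = brute_force_pauc(fp, sens, 0.25, 32.0)
        assert partial_auc(curve) == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# bootstrap + comparison


class TestBootstrap:
    def _cohort(self, seed, n_patients=12, shift=0.0):
        rng = np.random.default_rng(seed)
        patients = []
        for _ in range(n_patients):
            n_nodes = int(rng.integers(2, 5))
            det = rng.uniform(0.5 + shift, 1.0, size=rng.integers(1, n_nodes + 1))
            fps = rng.uniform(0.0, 0.7, size=rng.integers(3, 10))
            patients.append(_patient(det, fps, n_nodes))
        return patients

    def test_identical_patients_zero_width_bands(self):
        one = _patient([0.9, 0.6], [0.5, 0.4, 0.2], 3)
        boot = bootstrap_froc([one] * 8, n_boot=50, seed=0)
        np.testing.assert_allclose(boot.band_lo, boot.band_hi)
        assert boot.pauc_ci[0] == pytest.approx(boot.pauc_ci[1])

    def test_bands_contain_point_curve(self):
        patients = self._cohort(0)
        boot = bootstrap_froc(patients, n_boot=200, seed=1)
        from nodecad.evalstats import _sens_at_fp

        point = _sens_at_fp(froc_curve(patients), boot.band_fp_per_node)
        assert np.all(boot.band_lo - 1e-9 <= point)
        assert np.all(point <= boot.band_hi + 1e-9)

    def test_replicate_mean_close_to_point_estimate(self):
        patients = self._cohort(3, n_patients=20)
        boot = bootstrap_froc(patients, n_boot=400, seed=2)
        se = boot.pauc_replicates.std()
        assert abs(boot.pauc_replicates.mean() - boot.pauc) <= 2 * max(se, 1e-9)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_froc([_patient([0.9], [], 1)], n_boot=10)

    def test_deterministic_per_seed(self):
        patients = self._cohort(5)
        a = bootstrap_froc(patients, n_boot=50, seed=9)
        b = bootstrap_froc(patients, n_boot=50, seed=9)
        np.testing.assert_array_equal(a.pauc_replicates, b.pauc_replicates)


class TestCompareSystems:
    def test_identical_systems_give_half(self):
        reps = np.random.default_rng(0).normal(size=1000)
        raw, adj = compare_systems(reps, reps.copy(), n_comparisons=1)
        assert raw == pytest.approx(0.5, abs=0.01)

    def test_bonferroni_mapping(self):
        reps_a = np.zeros(99)
        # construct replicate sets with exactly 0 / 29 "B worse" outcomes
        b_better = np.ones(99)
        raw, adj = compare_systems(reps_a, b_better, n_comparisons=6)
        assert raw == pytest.approx(1 / 100)
        assert adj == pytest.approx(0.06)
        b_mixed = np.concatenate([np.full(29, -1.0), np.ones(70)])
        raw, adj = compare_systems(reps_a, b_mixed, n_comparisons=6)
        assert raw == pytest.approx(0.30)
        assert adj == 1.0  # capped

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_systems(np.zeros(10), np.zeros(11))

    @given(st.floats(0.001, 1.0), st.integers(1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bonferroni_monotone_and_capped(self, raw_target, m):
        n = 999
        k = int(round(raw_target * (n + 1))) - 1
        k = max(0, min(n, k))
        b = np.concatenate([np.full(k, -1.0), np.ones(n - k)])
        raw, adj = compare_systems(np.zeros(n), b, n_comparisons=m)
        assert adj == pytest.approx(min(1.0, raw * m))
        assert adj >= raw

    def test_paired_bootstrap_detects_better_system(self):
        rng = np.random.default_rng(0)
        base, better = [], []
        for _ in range(15):
            n_nodes = 3
            det = rng.uniform(0.4, 0.9, size=2)
            fps = rng.uniform(0.0, 0.8, size=8)
            base.append(_patient(det, fps, n_nodes))
            better.append(_patient(det + 0.1, fps * 0.5, n_nodes))
        boot = bootstrap_systems({"a": base, "b": better}, n_boot=300, seed=0)
        raw, adj = compare_systems(
            boot["a"].pauc_replicates, boot["b"].pauc_replicates, 1
        )
        assert raw < 0.05


# ---------------------------------------------------------------------------
# folds


class TestFolds:
    def test_equal_nodes_balance_exactly(self):
        split = stratified_patient_folds({i: 2 for i in range(10)}, k=5, seed=0)
        assert split.node_counts == [4] * 5

    def test_partition_disjoint_and_complete(self):
        counts = {i: (i % 4) + 1 for i in range(17)}
        split = stratified_patient_folds(counts, k=5, seed=1)
        members = [set(split.members(f)) for f in range(5)]
        assert set().union(*members) == set(counts)
        assert sum(len(m) for m in members) == len(counts)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_greedy_imbalance_bound(self, seed):
        rng = np.random.default_rng(seed)
        counts = {i: int(rng.integers(1, 9)) for i in range(int(rng.integers(5, 25)))}
        split = stratified_patient_folds(counts, k=5, seed=seed)
        assert max(split.node_counts) - min(split.node_counts) <= max(counts.values())

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            stratified_patient_folds({0: 1, 1: 1}, k=5)

    def test_cv_roles_partition_folds(self):
        for run in range(5):
            train, val, test = cv_run_roles(run, 5)
            assert sorted(train + [val, test]) == list(range(5))
            assert len(train) == 3


# ---------------------------------------------------------------------------
# supplementary reader


class TestReadFrocCsv:
    def test_comma_dialect_with_named_columns(self, tmp_path):
        path = tmp_path / "froc.csv"
        path.write_text("fp_per_node,sensitivity\n0.25,0.55\n2.0,0.80\n32.0,0.93\n")
        curve = read_froc_csv(str(path))
        np.testing.assert_allclose(curve.fp_per_node, [0.25, 2.0, 32.0])
        np.testing.assert_allclose(curve.sensitivity, [0.55, 0.80, 0.93])

    def test_tab_dialect_percent_sensitivity(self, tmp_path):
        path = tmp_path / "froc.tsv"
        path.write_text("fps\ttpr\n0.5\t60\n8\t85\n")
        curve = read_froc_csv(str(path))
        np.testing.assert_allclose(curve.sensitivity, [0.60, 0.85])

    def test_unnamed_numeric_columns(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("a,b\n0.1,0.2\n1.0,0.5\n")
        curve = read_froc_csv(str(path))
        assert partial_auc(curve, 0.25, 2.0) > 0
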