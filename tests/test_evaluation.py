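"""ROC sweeps, accuracies, confusion matrices and decision timelines."""

import numpy as np
import pytest

from emg_openset.evaluation import (
    accuracy_from_confusion,
    auc_trapezoid,
    confusion,
    decision_timeline,
    motion_accuracy,
    roc_sweep,
)
from emg_openset.grids import GridSpec
from emg_openset.novelty import NOVEL, Decision
from emg_openset.preprocessing import ActivityThreshold
from emg_openset.synthetic import RawRecording


def _decision(i, predicted, cnn_label=None):
    cnn_label = predicted if predicted != NOVEL else (cnn_label or "T1")
    return Decision(i, predicted, cnn_label, {})


class TestRocSweep:
    def test_perfect_separation_gives_auc_one(self, rng):
        cal = {"T1": rng.uniform(0.0, 0.3, size=50)}
        targets = rng.uniform(0.0, 0.3, size=(100, 1))
        novels = rng.uniform(0.7, 1.0, size=(100, 1))
        roc = roc_sweep(cal, targets, novels, ["T1"])
        assert roc.auc == pytest.approx(1.0)

    def test_identical_distributions_give_chance_auc(self):
        rng = np.random.default_rng(7)
        cal = {"T1": rng.uniform(size=2000)}
        targets = rng.uniform(size=(2000, 1))
        novels = rng.uniform(size=(2000, 1))
        roc = roc_sweep(cal, targets, novels, ["T1"])
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_trapezoid_arithmetic(self):
        assert auc_trapezoid([(0, 0), (0.5, 1.0), (1, 1)]) == pytest.approx(0.75)

    def test_empty_novel_set_rejected(self, rng):
        with pytest.raises(ValueError):
            roc_sweep({"T1": rng.uniform(size=10)}, rng.uniform(size=(5, 1)),
                      np.empty((0, 1)), ["T1"])

    def test_endpoints_present(self, rng):
        cal = {"T1": rng.uniform(size=30)}
        roc = roc_sweep(cal, rng.uniform(size=(30, 1)), rng.uniform(size=(30, 1)), ["T1"])
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_tpr_fpr_nondecreasing_in_recall(self, rng):
        from emg_openset.novelty import calibrate_thresholds
        cal = {t: rng.uniform(size=40) for t in ("T1", "T2")}
        targets = rng.uniform(size=(60, 2))
        novels = rng.uniform(size=(60, 2))
        prev_t = prev_f = -1.0
        for r in np.linspace(0, 1, 31):
            th = calibrate_thresholds(cal, float(r))
            tau = np.array([th.thresholds[t] for t in ("T1", "T2")])
            tpr = float(np.mean(np.any(targets <= tau, axis=1)))
            fpr = float(np.mean(np.any(novels <= tau, axis=1)))
            assert tpr >= prev_t and fpr >= prev_f
            prev_t, prev_f = tpr, fpr

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        cal = {"T1": rng.uniform(size=80), "T2": rng.uniform(size=80)}
        targets = rng.uniform(0, 0.8, size=(90, 2))
        novels = rng.uniform(0.2, 1.0, size=(90, 2))
        f = lambda s: np.square(s) / (1 + np.square(s))  # strictly increasing on [0, inf)
        roc_a = roc_sweep(cal, targets, novels, ["T1", "T2"])
        roc_b = roc_sweep({k: f(v) for k, v in cal.items()}, f(targets), f(novels), ["T1", "T2"])
        assert roc_b.auc == pytest.approx(roc_a.auc, abs=1e-12)


class TestMotionAccuracy:
    TARGETS = ["T1", "T2"]

    def test_fraction_of_correct_samples(self):
        decisions = [_decision(i, "T1") for i in range(18)] + [
            _decision(18, "T2"), _decision(19, NOVEL)
        ]
        truth = ["T1"] * 20
        acc = motion_accuracy(decisions, truth, self.TARGETS)
        assert acc["T1"] == pytest.approx(0.9)

    def test_closed_set_classifier_scores_zero_on_novels(self):
        decisions = [_decision(i, "T1") for i in range(10)]
        acc = motion_accuracy(decisions, ["N1"] * 10, self.TARGETS)
        assert acc["N1"] == 0.0

    def test_hand_built_mixed_stream(self):
        records = [
            ("T1", "T1", True), ("T1", "T2", False), ("T1", NOVEL, False),
            ("T2", "T2", True), ("T2", "T2", True),
            ("N1", NOVEL, True), ("N1", "T1", False),
            ("N2", NOVEL, True), ("N2", NOVEL, True), ("N2", "T2", False),
        ]
        decisions = [_decision(i, pred) for i, (_, pred, _) in enumerate(records)]
        truth = [t for t, _, _ in records]
        acc = motion_accuracy(decisions, truth, self.TARGETS)
        assert acc == {
            "T1": pytest.approx(1 / 3), "T2": pytest.approx(1.0),
            "N1": pytest.approx(1 / 2), "N2": pytest.approx(2 / 3),
        }

    def test_unknown_truth_label_rejected(self):
        with pytest.raises(ValueError):
            motion_accuracy([_decision(0, "T1")], [None], self.TARGETS)


class TestConfusion:
    TARGETS = ["T1", "T2"]

    def test_all_correct_fills_diagonal_and_novel_column(self):
        decisions = [_decision(0, "T1"), _decision(1, "T2"), _decision(2, NOVEL)]
        mat = confusion(decisions, ["T1", "T2", "N1"], self.TARGETS)
        assert mat.loc["T1", "T1"] == 1 and mat.loc["T2", "T2"] == 1
        assert mat.loc["N1", NOVEL] == 1
        assert mat.to_numpy().sum() == 3

    def test_row_sums_equal_class_counts(self, rng):
        preds = rng.choice(["T1", "T2", NOVEL], size=60)
        truth = rng.choice(["T1", "T2", "N1", "N2"], size=60)
        decisions = [_decision(i, p) for i, p in enumerate(preds)]
        mat = confusion(decisions, truth, self.TARGETS)
        for cls in np.unique(truth):
            assert mat.loc[cls].sum() == int(np.sum(truth == cls))

    def test_crafted_three_sample_matrix(self):
        decisions = [_decision(0, "T2"), _decision(1, NOVEL), _decision(2, "T1")]
        mat = confusion(decisions, ["T1", "T1", "N1"], self.TARGETS, ["N1"])
        assert mat.loc["T1", "T2"] == 1
        assert mat.loc["T1", NOVEL] == 1
        assert mat.loc["N1", "T1"] == 1
        assert mat.to_numpy().sum() == 3

    def test_accuracy_identity_with_confusion_matrix(self, rng):
        preds = rng.choice(["T1", "T2", NOVEL], size=200)
        truth = rng.choice(["T1", "T2", "N1", "N2"], size=200)
        decisions = [_decision(i, p) for i, p in enumerate(preds)]
        acc = motion_accuracy(decisions, truth, self.TARGETS)
        derived = accuracy_from_confusion(confusion(decisions, truth, self.TARGETS), self.TARGETS)
        assert acc == pytest.approx(derived)


class TestDecisionTimeline:
    def _stream(self, active_mask, rng, n_ch=4):
        sig = np.concatenate(
            [rng.normal(0, 1.0 if a else 0.001, (n_ch, 500)) for a in active_mask], axis=1
        )
        grid = GridSpec(rows=1, cols=n_ch)
        return RawRecording(signal=sig, fs=1000.0, grid=grid, task_id="T1")

    def test_one_decision_per_active_window_at_stream_rate(self, rng):
        rec = self._stream([True, True, True], rng)
        thr = ActivityThreshold(0.1)
        out = decision_timeline(rec, thr, lambda ws: [_decision(i, "T1") for i in range(len(ws))])
        starts = [s for s, _ in out]
        assert starts == list(range(0, 1500 - 250 + 1, 150))

    def test_all_rest_stream_yields_no_decisions(self, rng):
        rec = self._stream([False, False], rng)
        assert decision_timeline(rec, ActivityThreshold(0.1), lambda ws: []) == []

    def test_decision_count_equals_gated_window_count(self, rng):
        from emg_openset.preprocessing import gate_windows, segment_windows
        rec = self._stream([True, False, True, False], rng)
        thr = ActivityThreshold(0.1)
        expected = len(gate_windows(segment_windows(rec), thr))
        out = decision_timeline(rec, thr, lambda ws: [_decision(i, "T1") for i in range(len(ws))])
        assert len(out) == expected and 0 < expected < 26
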