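"""Autoencoder novelty detection: scores, calibration, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from emg_openset.novelty import (
    NOVEL,
    AutoencoderSpec,
    ThresholdTable,
    anomaly_score,
    bray_curtis,
    calibrate_thresholds,
    decide_scores,
    train_autoencoders,
)

TINY_SPEC = AutoencoderSpec(
    layer_widths=(8, 4, 2, 4, 8), batch_size=4, lr_schedule=((0.1, 150), (0.01, 50)), seed=3
)


def bc_loop_oracle(x, xhat):
    num = den = 0.0
    for a, b in zip(x, xhat):
        num += abs(a - b)
        den += a + b
    return num / den if den else 0.0


class TestBrayCurtis:
    def test_identity_scores_zero(self):
        assert bray_curtis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_support_scores_one(self):
        assert bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_direct_evaluation(self):
        assert bray_curtis([2.0, 1.0, 1.0], [1.0, 1.0, 0.0]) == pytest.approx(1 / 3)

    def test_all_zero_pair_guarded_to_zero(self):
        assert bray_curtis([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_matches_loop_and_scipy_oracles(self, rng):
        for _ in range(100):
            x = rng.uniform(0, 5, size=16)
            xhat = rng.uniform(0, 5, size=16)
            ours = bray_curtis(x, xhat)
            assert ours == pytest.approx(bc_loop_oracle(x, xhat), abs=1e-12)
            assert ours == pytest.approx(scipy_braycurtis(x, xhat), abs=1e-12)

    @given(
        hnp.arrays(np.float64, 12, elements=st.floats(0, 1e6)),
        hnp.arrays(np.float64, 12, elements=st.floats(0, 1e6)),
    )
    @settings(max_examples=100, deadline=None)
    def test_range_on_nonnegative_vectors(self, x, xhat):
        e = bray_curtis(x, xhat)
        assert 0.0 <= e <= 1.0

    def test_batch_rows_match_scalar_calls(self, rng):
        x = rng.uniform(0, 1, size=(5, 8))
        xhat = rng.uniform(0, 1, size=(5, 8))
        batch = bray_curtis(x, xhat)
        for i in range(5):
            assert batch[i] == pytest.approx(bray_curtis(x[i], xhat[i]))


class TestCalibration:
    def test_order_statistic_rule(self):
        scores = {"T1": np.arange(0.1, 1.05, 0.1)}
        th = calibrate_thresholds(scores, 0.85)
        assert th.thresholds["T1"] == pytest.approx(0.9)  # ceil(8.5) = 9th smallest

    def test_full_recall_accepts_every_calibration_sample(self, rng):
        scores = {"T1": rng.uniform(size=50)}
        th = calibrate_thresholds(scores, 1.0)
        assert th.thresholds["T1"] == scores["T1"].max()
        assert np.all(scores["T1"] <= th.thresholds["T1"])

    def test_zero_recall_accepts_nothing(self, rng):
        scores = {"T1": rng.uniform(size=20)}
        th = calibrate_thresholds(scores, 0.0)
        assert not np.any(scores["T1"] <= th.thresholds["T1"])

    def test_recall_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds({"T1": [0.1]}, 1.2)

    def test_thresholds_nondecreasing_in_recall(self, rng):
        scores = {t: rng.uniform(size=rng.integers(5, 60)) for t in ("T1", "T2", "T3")}
        grid = np.linspace(0, 1, 21)
        prev = {t: -np.inf for t in scores}
        for r in grid:
            th = calibrate_thresholds(scores, float(r))
            for t in scores:
                assert th.thresholds[t] >= prev[t]
                prev[t] = th.thresholds[t]

    def test_acceptance_at_least_recall_and_minimal(self, rng):
        scores = {"T1": rng.uniform(size=37)}
        for r in np.linspace(0.05, 1.0, 20):
            th = calibrate_thresholds(scores, float(r))
            s = np.sort(scores["T1"])
            accepted = np.mean(s <= th.thresholds["T1"])
            assert accepted >= r
            # smallest such order statistic: the next-lower one undershoots r
            k = int(np.ceil(r * len(s)))
            if k >= 2:
                assert np.mean(s <= s[k - 2]) < r


class TestAutoencoderTraining:
    def test_memorizes_duplicated_vector(self, rng):
        v = rng.uniform(0.2, 1.0, size=8).astype(np.float32)
        x = np.tile(v, (32, 1))
        aes = train_autoencoders({"T1": x}, TINY_SPEC, embed_scale=1.0)
        recon = aes.models["T1"].reconstruct(v)
        assert float(np.mean((recon - v) ** 2)) < 1e-3

    def test_one_model_per_task_group(self, rng):
        groups = {f"T{i}": rng.uniform(0, 1, size=(8, 8)) for i in range(1, 8)}
        spec = AutoencoderSpec(layer_widths=(8, 4, 2, 4, 8), batch_size=4,
                               lr_schedule=((0.05, 5),), seed=0)
        aes = train_autoencoders(groups, spec)
        assert sorted(aes.models) == [f"T{i}" for i in range(1, 8)]

    def test_empty_group_rejected_with_task_name(self):
        with pytest.raises(ValueError, match="T2"):
            train_autoencoders({"T1": np.ones((4, 8)), "T2": np.empty((0, 8))}, TINY_SPEC)

    def test_default_schedule(self):
        assert AutoencoderSpec().lr_schedule == ((0.1, 600), (0.01, 300))
        widths = AutoencoderSpec().layer_widths
        assert widths[0] == widths[-1] == 512 and min(widths) < 512

    def test_bottleneck_must_compress(self):
        with pytest.raises(ValueError):
            AutoencoderSpec(layer_widths=(8, 8, 8))

    def test_anomaly_score_low_on_training_task_high_elsewhere(self, rng):
        x = rng.uniform(0.5, 1.0, size=(40, 8)) * np.array([1, 1, 1, 1, 0.1, 0.1, 0.1, 0.1])
        aes = train_autoencoders({"T1": x}, TINY_SPEC, embed_scale=1.0)
        own = anomaly_score(aes.models["T1"], x[0])
        other = anomaly_score(aes.models["T1"], x[0][::-1].copy())
        assert own < other


class TestDecisions:
    TASKS = ["T1", "T2"]

    def test_all_scores_above_thresholds_is_novel(self):
        th = ThresholdTable(0.5, {"T1": 0.1, "T2": 0.1})
        d = decide_scores(np.array([[0.5, 0.6]]), ["T1"], self.TASKS, th)[0]
        assert d.predicted == NOVEL

    def test_predicted_class_fit_accepted_under_both_rules(self):
        th = ThresholdTable(0.5, {"T1": 0.3, "T2": 0.1})
        for rule in ("any_accept", "predicted_class"):
            d = decide_scores(np.array([[0.2, 0.9]]), ["T1"], self.TASKS, th, rule)[0]
            assert d.predicted == "T1"

    def test_rules_differ_when_only_other_task_fits(self):
        # classifier says T1, but only T2's autoencoder fits the probe
        th = ThresholdTable(0.5, {"T1": 0.1, "T2": 0.5})
        scores = np.array([[0.4, 0.3]])
        any_d = decide_scores(scores, ["T1"], self.TASKS, th, "any_accept")[0]
        strict_d = decide_scores(scores, ["T1"], self.TASKS, th, "predicted_class")[0]
        assert any_d.predicted == "T1"  # accepted, labelled by the classifier
        assert strict_d.predicted == NOVEL

    def test_task_order_mismatch_rejected(self):
        th = ThresholdTable(0.5, {"T1": 0.1})
        with pytest.raises(ValueError):
            decide_scores(np.array([[0.1, 0.2]]), ["T1"], self.TASKS, th)

    def test_unknown_rule_rejected(self):
        th = ThresholdTable(0.5, {"T1": 0.1, "T2": 0.1})
        with pytest.raises(ValueError):
            decide_scores(np.array([[0.1, 0.2]]), ["T1"], self.TASKS, th, rule="vote")

    def test_raising_recall_never_revokes_acceptance(self, rng):
        cal = {t: rng.uniform(size=30) for t in self.TASKS}
        probes = rng.uniform(size=(50, 2))
        labels = ["T1"] * 50
        accepted_prev = np.zeros(50, dtype=bool)
        for r in np.linspace(0, 1, 11):
            th = calibrate_thresholds(cal, float(r))
            dec = decide_scores(probes, labels, self.TASKS, th)
            accepted = np.array([d.predicted != NOVEL for d in dec])
            assert np.all(accepted | ~accepted_prev)
            accepted_prev = accepted
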