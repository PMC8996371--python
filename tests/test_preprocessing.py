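"""Windowing, activity gating, feature images and splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emg_openset.grids import GridSpec
from emg_openset.preprocessing import (
    ActivityThreshold,
    Window,
    feature_image,
    fit_activity_threshold,
    gate_windows,
    segment_windows,
    split_dataset,
    window_activity,
)
from emg_openset.synthetic import REST_LABEL, RawRecording


def _rec(signal, grid=None, baseline=False, fs=1000.0):
    grid = grid or GridSpec(rows=1, cols=signal.shape[0])
    return RawRecording(
        signal=np.asarray(signal, dtype=float),
        fs=fs,
        grid=grid,
        task_id=REST_LABEL if baseline else "T1",
        baseline=baseline,
    )


class TestSegmentation:
    def test_five_second_recording_default_windows(self):
        rec = _rec(np.zeros((2, 5000)))
        assert len(segment_windows(rec)) == 32  # floor((5000-250)/150)+1

    def test_exactly_one_window_at_boundary(self):
        rec = _rec(np.zeros((2, 250)))
        windows = segment_windows(rec)
        assert len(windows) == 1 and windows[0].data.shape == (2, 250)

    def test_shorter_than_window_yields_empty(self):
        assert segment_windows(_rec(np.zeros((2, 100)))) == []

    def test_windows_ordered_and_sized(self):
        rec = _rec(np.arange(4000, dtype=float).reshape(2, 2000))
        windows = segment_windows(rec, 250, 150)
        starts = [w.source[2] for w in windows]
        assert starts == sorted(starts)
        assert all(w.data.shape[1] == 250 for w in windows)

    @given(
        n=st.integers(1, 3000),
        win=st.integers(1, 400),
        inc=st.integers(1, 400),
    )
    @settings(max_examples=60, deadline=None)
    def test_window_count_matches_enumeration_oracle(self, n, win, inc):
        rec = _rec(np.zeros((1, n)), fs=1000.0)
        got = len(segment_windows(rec, win_ms=win, inc_ms=inc))
        # oracle: enumerate every valid start position
        expected = sum(1 for s in range(0, n, inc) if s + win <= n)
        assert got == expected


class TestActivityThreshold:
    def test_zero_baseline_gives_zero(self):
        thr = fit_activity_threshold(_rec(np.zeros((3, 100)), baseline=True))
        assert thr.value == 0.0

    def test_constant_baseline_gives_constant(self):
        thr = fit_activity_threshold(_rec(np.full((3, 100), -2.0), baseline=True))
        assert thr.value == pytest.approx(2.0)

    def test_two_channel_toy_hand_computed(self):
        # ch0: |x| = [1, 3] -> mean 2, sd 1 -> 5 ; ch1: |x| = [2, 2] -> 2, 0 -> 2
        sig = np.array([[1.0, -3.0], [2.0, 2.0]])
        thr = fit_activity_threshold(_rec(sig, baseline=True))
        assert thr.value == pytest.approx((5.0 + 2.0) / 2.0)

    def test_requires_baseline_flag(self):
        with pytest.raises(ValueError):
            fit_activity_threshold(_rec(np.zeros((2, 10)), baseline=False))


class TestGating:
    def test_zero_threshold_keeps_nonzero_window(self):
        w = Window(np.ones((2, 10)), ("T1", 0, 0))
        assert gate_windows([w], ActivityThreshold(0.0)) == [w]

    def test_zero_window_dropped_by_positive_threshold(self):
        w = Window(np.zeros((2, 10)), ("T1", 0, 0))
        assert gate_windows([w], ActivityThreshold(0.1)) == []

    def test_gating_monotone_in_threshold(self, rng):
        windows = [Window(rng.normal(0, s, (3, 50)), ("T1", 0, i)) for i, s in
                   enumerate(np.linspace(0.01, 2.0, 25))]
        for lo, hi in [(0.0, 0.3), (0.3, 0.8), (0.1, 1.5)]:
            kept_hi = {id(w) for w in gate_windows(windows, ActivityThreshold(hi))}
            kept_lo = {id(w) for w in gate_windows(windows, ActivityThreshold(lo))}
            assert kept_hi <= kept_lo

    def test_annotated_rest_active_transitions(self, rng):
        """Only windows from the active segment survive the fitted gate."""
        fs = 1000.0
        rest = rng.normal(0, 0.02, (4, 1000))
        active = rng.normal(0, 1.0, (4, 1500))
        rec = _rec(np.concatenate([rest, active, rest], axis=1), fs=fs)
        thr = fit_activity_threshold(_rec(rest, baseline=True))
        kept = gate_windows(segment_windows(rec), thr)
        starts = {w.source[2] for w in kept}
        for w in segment_windows(rec):
            s = w.source[2]
            fully_active = 1000 <= s and s + 250 <= 2500
            fully_rest = s + 250 <= 1000 or s >= 2500
            if fully_active:
                assert s in starts
            if fully_rest:
                assert s not in starts


class TestFeatureImage:
    def test_alternating_channel_values(self):
        grid = GridSpec(rows=1, cols=1)
        w = Window(np.array([[3.0, -3.0, 3.0, -3.0]]), ("T1", 0, 0))
        img = feature_image(w, grid)
        mav, wl, rms = img.values[0, 0]
        assert (mav, rms) == pytest.approx((3.0, 3.0))
        assert wl == pytest.approx(18.0)

    def test_zero_window_zero_image(self, grid):
        w = Window(np.zeros((96, 50)), ("T1", 0, 0))
        assert np.all(feature_image(w, grid).values == 0)

    def test_constant_channel(self):
        grid = GridSpec(rows=1, cols=1)
        w = Window(np.full((1, 64), -1.7), ("T1", 0, 0))
        mav, wl, rms = feature_image(w, grid).values[0, 0]
        assert (mav, rms, wl) == pytest.approx((1.7, 1.7, 0.0))

    def test_channel_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            feature_image(Window(np.zeros((5, 50)), ("T1", 0, 0)), grid)

    def test_placement_follows_channel_order(self):
        grid = GridSpec(rows=2, cols=2)
        data = np.zeros((4, 10))
        data[grid.channel_of(1, 0)] = 2.0
        img = feature_image(Window(data, ("T1", 0, 0)), grid)
        assert img.values[1, 0, 0] == pytest.approx(2.0)
        assert img.values[0, 0, 0] == 0.0

    def test_sign_flip_and_offset_invariances(self, rng):
        grid = GridSpec(rows=2, cols=3)
        data = rng.normal(size=(6, 100))
        base = feature_image(Window(data, ("T1", 0, 0)), grid).values
        flipped = feature_image(Window(-data, ("T1", 0, 0)), grid).values
        np.testing.assert_allclose(flipped[..., 0], base[..., 0])  # MAV
        np.testing.assert_allclose(flipped[..., 2], base[..., 2])  # RMS
        shifted = feature_image(Window(data + 5.0, ("T1", 0, 0)), grid).values
        np.testing.assert_allclose(shifted[..., 1], base[..., 1], atol=1e-9)  # WL


class TestSplit:
    def test_single_class_100_samples(self):
        split = split_dataset(["a"] * 100, seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (64, 16, 20)

    def test_same_seed_identical(self):
        labels = ["a"] * 20 + ["b"] * 30
        s1 = split_dataset(labels, seed=4)
        s2 = split_dataset(labels, seed=4)
        for a, b in zip((s1.train, s1.validation, s1.test), (s2.train, s2.validation, s2.test)):
            np.testing.assert_array_equal(a, b)

    def test_largest_remainder_counts_seven_classes(self):
        labels = np.repeat([f"T{i}" for i in range(1, 8)], 10)
        split = split_dataset(labels, seed=1)
        for cls in np.unique(labels):
            counts = tuple(
                int(np.sum(labels[idx] == cls))
                for idx in (split.train, split.validation, split.test)
            )
            assert counts == (6, 2, 2)

    def test_disjoint_cover_and_proportions(self, rng):
        labels = rng.choice(["a", "b", "c"], size=200, p=[0.5, 0.3, 0.2])
        split = split_dataset(labels, seed=3)
        combined = np.sort(np.concatenate([split.train, split.validation, split.test]))
        np.testing.assert_array_equal(combined, np.arange(len(labels)))
        for cls in "abc":
            n = np.sum(labels == cls)
            for idx, frac in zip((split.train, split.validation, split.test), (0.64, 0.16, 0.20)):
                assert abs(np.sum(labels[idx] == cls) - frac * n) <= 1.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a"] * 10, fractions=(0.7, 0.2, 0.2))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a"] * 4 + ["b"] * 10)


def test_window_activity_is_mean_rectified_amplitude(rng):
    data = rng.normal(size=(5, 40))
    w = Window(data, ("T1", 0, 0))
    assert window_activity(w) == pytest.approx(np.mean(np.abs(data)))
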