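"""Windowing, activity gating, feature images and dataset splits.

Recordings are cut into overlapping analysis windows (250 ms length, 150 ms
increment by default).  Windows of quiescent signal are discarded by an
amplitude gate whose threshold is fitted on a baseline recording as the
rectified mean plus three standard deviations, per channel, averaged over all
channels.  Each surviving window becomes a rows x cols x 3 "feature image"
holding the per-electrode mean absolute value (MAV), waveform length (WL) and
root mean square (RMS).  Target-task samples are split 64/16/20 into
train/validation/test, stratified per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec
from .synthetic import RawRecording

logger = logging.getLogger(__name__)

FEATURE_ORDER = ("MAV", "WL", "RMS")
DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)


@dataclass
class Window:
    """One analysis window: ``data`` is channels x L."""

    data: np.ndarray
    source: tuple[str, int, int]  # (task_id, rep_index, start_sample)

    @property
    def task_id(self) -> str:
        return self.source[0]


@dataclass
class FeatureImage:
    """Per-window electrode-grid feature array, shape (rows, cols, 3)."""

    values: np.ndarray
    label: str
    feature_order: tuple[str, ...] = FEATURE_ORDER
    source: tuple[str, int, int] | None = None


@dataclass
class ActivityThreshold:
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("activity threshold must be nonnegative")


@dataclass
class DatasetSplit:
    """Disjoint index sets over one sample collection."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")


def segment_windows(
    rec: RawRecording, win_ms: float = 250.0, inc_ms: float = 150.0
) -> list[Window]:
    """Cut a recording into overlapping windows ordered by start sample.

    Yields ``floor((n_samples - win) / inc) + 1`` windows; a recording shorter
    than one window yields an empty list (logged, not an error).
    """
    win = int(round(win_ms * rec.fs / 1000.0))
    inc = int(round(inc_ms * rec.fs / 1000.0))
    if win < 1 or inc < 1:
        raise ValueError("window and increment must be at least one sample")
    n = rec.n_samples
    if n < win:
        logger.info("recording %s shorter than one window; no windows emitted", rec.task_id)
        return []
    starts = range(0, n - win + 1, inc)
    return [
        Window(rec.signal[:, s : s + win], (rec.task_id, rec.rep_index, s)) for s in starts
    ]


def fit_activity_threshold(baseline: RawRecording) -> ActivityThreshold:
    """Rest-activity gate level from a quiescent recording.

    Per channel, the mean plus three standard deviations of the rectified
    signal; the threshold is the average of that statistic over all channels.
    """
    if not baseline.baseline:
        raise ValueError("threshold must be fitted on a baseline-flagged recording")
    if baseline.n_samples == 0:
        raise ValueError("empty baseline recording")
    rect = np.abs(baseline.signal)
    per_channel = rect.mean(axis=1) + 3.0 * rect.std(axis=1)
    return ActivityThreshold(float(per_channel.mean()))


def window_activity(w: Window) -> float:
    """Mean absolute amplitude over all channels and samples."""
    return float(np.mean(np.abs(w.data)))


def gate_windows(windows: list[Window], thr: ActivityThreshold) -> list[Window]:
    """Keep windows whose mean absolute amplitude exceeds the threshold."""
    return [w for w in windows if window_activity(w) > thr.value]


def _features_per_channel(data: np.ndarray) -> np.ndarray:
    """(channels, 3) array of MAV, WL, RMS for a channels x L window."""
    mav = np.mean(np.abs(data), axis=1)
    wl = np.sum(np.abs(np.diff(data, axis=1)), axis=1)
    rms = np.sqrt(np.mean(data.astype(np.float64) ** 2, axis=1))
    return np.stack([mav, wl, rms], axis=1)


def feature_image(w: Window, grid: GridSpec) -> FeatureImage:
    """MAV/WL/RMS of each channel arranged on the electrode grid."""
    if w.data.shape[0] != grid.n_channels:
        raise ValueError(
            f"window has {w.data.shape[0]} channels, grid expects {grid.n_channels}"
        )
    feats = _features_per_channel(w.data)  # (channels, 3)
    values = np.empty((grid.rows, grid.cols, 3))
    for ch in range(grid.n_channels):
        r, c = grid.position_of(ch)
        values[r, c, :] = feats[ch]
    return FeatureImage(values=values, label=w.task_id, source=w.source)


def split_dataset(
    labels,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified, seeded train/validation/test split over sample indices.

    Per-class counts follow a largest-remainder rounding of the requested
    fractions, so totals are exact and per-class proportions are within one
    sample of target.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three numbers summing to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 5:
            raise ValueError(f"class {cls!r} has fewer than 5 samples")
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        cuts = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.append(chunk)
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return DatasetSplit(train, val, test, fractions)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    ideal = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in ideal]
    short = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (ideal[i] - base[i]), reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base
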