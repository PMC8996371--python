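"""Open-set evaluation: ROC over the recall-factor sweep, per-motion accuracy,
confusion matrices and decision-stream timelines.

The ROC convention is rejection-stage only: positives are target-task test
samples, so TPR(r) is the fraction of target samples *accepted* at recall
factor r and FPR(r) the fraction of novel samples accepted — whether an
accepted target sample is then classified to the right task is scored
separately by the per-motion accuracy.  AUC is the trapezoid rule over
FPR-sorted points with the degenerate accept-none (0,0) and accept-all (1,1)
endpoints included; FPR ties keep the maximum TPR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .novelty import NOVEL, Decision, calibrate_thresholds

DEFAULT_R_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (FPR, TPR), sorted by FPR
    auc: float
    r_grid: np.ndarray | None = None


def _accept_fraction(scores: np.ndarray, tau: np.ndarray) -> float:
    """Fraction of rows with any score within its task threshold (inf-safe)."""
    with np.errstate(invalid="ignore"):
        accepted = np.any(scores <= tau, axis=1)
    return float(np.mean(accepted))


def auc_trapezoid(points) -> float:
    """Trapezoid-rule AUC over (FPR, TPR) points; FPR ties resolved to max TPR."""
    best: dict[float, float] = {}
    for fpr, tpr in points:
        best[round(float(fpr), 12)] = max(best.get(round(float(fpr), 12), 0.0), float(tpr))
    fprs = np.array(sorted(best))
    tprs = np.array([best[f] for f in fprs])
    return float(np.trapezoid(tprs, fprs))


def roc_sweep(
    calibration_scores: dict[str, np.ndarray],
    target_scores: np.ndarray,
    novel_scores: np.ndarray,
    task_order: list[str] | None = None,
    r_grid: np.ndarray | None = None,
) -> RocCurve:
    """ROC of a per-task-threshold detector swept over the shared recall factor.

    ``target_scores`` / ``novel_scores`` are (n, K) anomaly-score matrices of
    the test sets (rows are probes, columns tasks in ``task_order``; a column
    may be +inf where a detector scores only the predicted class).  For each r
    the per-task thresholds are recalibrated from ``calibration_scores``; a
    probe is accepted if any column is within its threshold.
    """
    if len(novel_scores) == 0:
        raise ValueError("novel test set is empty")
    if task_order is None:
        task_order = sorted(calibration_scores)
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    if r_grid.min() > 0.0 or r_grid.max() < 1.0:
        raise ValueError("r_grid must span [0, 1]")
    target_scores = np.atleast_2d(target_scores)
    novel_scores = np.atleast_2d(novel_scores)
    points = [(0.0, 0.0), (1.0, 1.0)]  # accept-none / accept-all endpoints
    for r in r_grid:
        th = calibrate_thresholds(calibration_scores, float(r))
        tau = np.array([th.thresholds[t] for t in task_order])
        points.append((_accept_fraction(novel_scores, tau), _accept_fraction(target_scores, tau)))
    points.sort(key=lambda p: (p[0], p[1]))
    return RocCurve(points=points, auc=auc_trapezoid(points), r_grid=r_grid)


def motion_accuracy(
    decisions: list[Decision], truth, target_labels: list[str]
) -> dict[str, float]:
    """Per-motion accuracy; all novel tasks share the single NOVEL label.

    A target sample is correct iff accepted and classified to its own task;
    a novel sample is correct iff rejected as NOVEL.  Returned per true task
    (novel tasks individually, as recorded in ``truth``).
    """
    truth = list(truth)
    if len(truth) != len(decisions):
        raise ValueError("decisions and truth labels differ in length")
    per_task: dict[str, list[bool]] = {}
    for d, t in zip(decisions, truth):
        if t in target_labels:
            correct = d.predicted == t
        elif isinstance(t, str):
            correct = d.predicted == NOVEL
        else:
            raise ValueError(f"unknown truth label {t!r}")
        per_task.setdefault(t, []).append(correct)
    return {t: float(np.mean(v)) for t, v in per_task.items()}


def confusion(
    decisions: list[Decision],
    truth,
    target_labels: list[str],
    novel_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Count matrix: rows are true tasks (targets then novels), columns the
    predicted target tasks plus NOVEL.  Row sums equal per-class counts."""
    truth = list(truth)
    if novel_labels is None:
        novel_labels = sorted({t for t in truth if t not in target_labels})
    rows = list(target_labels) + list(novel_labels)
    cols = list(target_labels) + [NOVEL]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for d, t in zip(decisions, truth):
        mat.loc[t, d.predicted] += 1
    return mat


def accuracy_from_confusion(mat: pd.DataFrame, target_labels: list[str]) -> dict[str, float]:
    """Per-motion accuracies implied by a confusion matrix (cross-check identity)."""
    out = {}
    for t in mat.index:
        row = mat.loc[t]
        total = int(row.sum())
        if total == 0:
            continue
        correct = int(row[t]) if t in target_labels else int(row[NOVEL])
        out[t] = correct / total
    return out


def decision_timeline(rec, thr, decide_fn, win_ms: float = 250.0, inc_ms: float = 150.0):
    """Decision stream over a continuous recording: one decision per active window.

    Windows are cut at the configured increment (6.67 Hz at the 150 ms
    default), gated by the activity threshold, and passed to ``decide_fn``
    (windows -> decisions).  Returns ``[(start_sample, Decision), ...]``.
    """
    from .preprocessing import gate_windows, segment_windows

    windows = gate_windows(segment_windows(rec, win_ms, inc_ms), thr)
    if not windows:
        return []
    decisions = decide_fn(windows)
    return [(w.source[2], d) for w, d in zip(windows, decisions)]
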