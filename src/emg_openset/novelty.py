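"""Autoencoder novelty detection over CNN embeddings.

One dense autoencoder is trained per target task, on that task's embeddings
only (512 -> 256 -> 64 -> 256 -> 512 by default, ReLU on the hidden layers;
the output layer is trained linear and its reconstruction clamped at zero
when scoring, so reconstructions stay nonnegative without the dead-unit
pathology a rectified regression output suffers under plain SGD).  Training
minimizes mean squared error with mini-batch SGD (batch 16, learning rate 0.1
for 600 epochs then 0.01 for 300).  At test time a probe's anomaly score for task k is the
Bray-Curtis distance between the embedding and its reconstruction,

    E = sum_k |x_k - xhat_k| / sum_k (x_k + xhat_k),

which lies in [0, 1] for nonnegative data: 0 for a perfect reconstruction,
1 for disjoint support.

Per-task acceptance thresholds are calibrated from validation-set scores via a
shared recall factor r: the threshold for task k is the ceil(r * n_k)-th
smallest of that task's own calibration scores, so at least a fraction r of
calibration samples is accepted.  A probe is accepted if some task's
autoencoder fits it (``any_accept``, the default) or if the classifier's
predicted task does (``predicted_class``); accepted probes take the
classifier's label, everything else is rejected as NOVEL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .cnn import TrainedCNN, embed, predict_proba

logger = logging.getLogger(__name__)

NOVEL = "NOVEL"
DECISION_RULES = ("any_accept", "predicted_class")


@dataclass
class AutoencoderSpec:
    layer_widths: tuple[int, ...] = (512, 256, 128, 256, 512)
    batch_size: int = 16
    lr_schedule: tuple[tuple[float, int], ...] = ((0.1, 600), (0.01, 300))
    max_grad_norm: float = 5.0  # divergence guard for the early large-lr steps
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.layer_widths
        if w[0] != w[-1]:
            raise ValueError("first and last layer widths must equal the embedding length")
        if min(w) >= w[0]:
            raise ValueError("bottleneck must be narrower than the input")


@dataclass
class Autoencoder:
    net: nn.Sequential
    spec: AutoencoderSpec
    task_id: str

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Nonnegative reconstruction (linear output clamped at zero)."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 1
        out = np.maximum(self.net.forward(x[None] if single else x, train=False), 0.0)
        return out[0] if single else out


@dataclass
class AutoencoderSet:
    models: dict[str, Autoencoder]
    task_order: list[str]
    embed_scale: float = 1.0  # scalar divisor applied to embeddings

    def __post_init__(self) -> None:
        if set(self.models) != set(self.task_order):
            raise ValueError("exactly one autoencoder per target task required")


@dataclass
class ThresholdTable:
    recall_factor: float
    thresholds: dict[str, float]


@dataclass
class Decision:
    probe_id: int
    predicted: str  # a target-task label or NOVEL
    cnn_label: str
    scores: dict[str, float]
    rule: str = "any_accept"

    def __post_init__(self) -> None:
        if self.predicted != NOVEL and self.predicted != self.cnn_label:
            raise ValueError("an accepted probe must carry the classifier's label")


# ---------------------------------------------------------------------------
# Bray-Curtis anomaly score
# ---------------------------------------------------------------------------

def bray_curtis(x, xhat) -> float | np.ndarray:
    """Bray-Curtis distance sum|x - xhat| / sum(x + xhat) along the last axis.

    Defined here for nonnegative vectors; an all-zero pair scores 0 (a perfect
    reconstruction of nothing), guarding the zero denominator.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    num = np.abs(x - xhat).sum(axis=-1)
    den = (x + xhat).sum(axis=-1)
    zero = den == 0
    if np.any(zero):
        logger.debug("all-zero vector pair in bray_curtis; scoring 0")
    out = np.divide(num, den, out=np.zeros_like(num), where=~zero)
    return float(out) if out.ndim == 0 else out


def anomaly_score(model: Autoencoder, x, scale: float = 1.0):
    """Reconstruction anomaly score(s) of embedding(s) ``x`` under one task model."""
    x = np.asarray(x, dtype=np.float32) / scale
    return bray_curtis(x, model.reconstruct(x))


def score_matrix(aes: AutoencoderSet, embeddings: np.ndarray) -> np.ndarray:
    """(n, K) anomaly scores of each embedding under each task's autoencoder."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float32))
    cols = [
        anomaly_score(aes.models[task], embeddings, aes.embed_scale)
        for task in aes.task_order
    ]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _build_autoencoder(spec: AutoencoderSpec, task_id: str, rng: np.random.Generator) -> Autoencoder:
    layers: list[nn.Layer] = []
    widths = spec.layer_widths
    for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
        dense = nn.Dense(n_in, n_out, rng)
        # small positive bias keeps rectified units alive at initialization
        dense.b[...] = 0.1
        layers.append(dense)
        if i < len(widths) - 2:  # hidden layers only; output stays linear
            layers.append(nn.ReLU())
    return Autoencoder(nn.Sequential(layers), spec, task_id)


def train_autoencoders(
    embeddings_by_task: dict[str, np.ndarray],
    spec: AutoencoderSpec | None = None,
    embed_scale: float | None = None,
) -> AutoencoderSet:
    """Train one autoencoder per target task on that task's embeddings only.

    ``embed_scale`` (a single scalar divisor, the RMS of all training
    embedding values by default) conditions the regression without changing
    Bray-Curtis scores, which are invariant to a common scaling of input and
    reconstruction.
    """
    spec = spec or AutoencoderSpec()
    if not embeddings_by_task:
        raise ValueError("no task groups supplied")
    for task, x in embeddings_by_task.items():
        if len(x) == 0:
            raise ValueError(f"task {task!r} has no embeddings to train on")
    if embed_scale is None:
        total = np.concatenate([np.asarray(v).ravel() for v in embeddings_by_task.values()])
        m = float(np.sqrt(np.mean(np.square(total, dtype=np.float64))))
        embed_scale = m if m > 0 else 1.0
    task_order = sorted(embeddings_by_task)
    root = np.random.SeedSequence(spec.seed)
    models: dict[str, Autoencoder] = {}
    loss_fn = nn.MeanSquaredError()
    for task, seed in zip(task_order, root.spawn(len(task_order))):
        rng = np.random.default_rng(seed)
        ae = _build_autoencoder(spec, task, rng)
        x = (np.asarray(embeddings_by_task[task], dtype=np.float32) / embed_scale)
        opt = nn.SGD(lr=spec.lr_schedule[0][0])
        epoch = 0
        for lr, n_epochs in spec.lr_schedule:
            opt.lr = lr
            for _ in range(n_epochs):
                for batch in nn.minibatches(len(x), spec.batch_size, rng):
                    xb = x[batch]
                    out = ae.net.forward(xb, train=True, rng=rng)
                    loss, grad = loss_fn.loss_and_grad(out, xb)
                    if not math.isfinite(loss):
                        raise RuntimeError(
                            f"non-finite autoencoder loss (task {task}, epoch {epoch})"
                        )
                    ae.net.backward(grad)
                    if spec.max_grad_norm:
                        total = math.sqrt(
                            sum(float(np.sum(np.square(g, dtype=np.float64))) for g in ae.net.grads)
                        )
                        if total > spec.max_grad_norm:
                            for g in ae.net.grads:
                                g *= spec.max_grad_norm / total
                    opt.step(ae.net.params, ae.net.grads)
                epoch += 1
        models[task] = ae
    return AutoencoderSet(models, task_order, embed_scale)


# ---------------------------------------------------------------------------
# threshold calibration and decisions
# ---------------------------------------------------------------------------

def calibrate_thresholds(scores_by_task: dict[str, np.ndarray], r: float) -> ThresholdTable:
    """Per-task thresholds at a shared recall factor ``r``.

    The threshold for task k is the ceil(r * n_k)-th smallest calibration
    score, so the achieved acceptance fraction (score <= threshold, inclusive)
    is at least r.  r = 0 yields a threshold below every score (nothing
    accepted); r = 1 yields the maximum score.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("recall factor must lie in [0, 1]")
    thresholds = {}
    for task, scores in scores_by_task.items():
        scores = np.sort(np.asarray(scores, dtype=float))
        if len(scores) == 0:
            raise ValueError(f"no calibration scores for task {task!r}")
        k = math.ceil(r * len(scores))
        thresholds[task] = -np.inf if k == 0 else float(scores[k - 1])
    return ThresholdTable(recall_factor=r, thresholds=thresholds)


def decide_scores(
    scores: np.ndarray,
    cnn_labels,
    aes_task_order: list[str],
    th: ThresholdTable,
    rule: str = "any_accept",
) -> list[Decision]:
    """Accept/reject probes given precomputed (n, K) anomaly scores."""
    if rule not in DECISION_RULES:
        raise ValueError(f"unknown decision rule {rule!r}")
    if set(aes_task_order) != set(th.thresholds):
        raise ValueError("threshold table does not match the autoencoder task order")
    tau = np.array([th.thresholds[t] for t in aes_task_order])
    scores = np.atleast_2d(scores)
    decisions = []
    for i, (row, cnn_label) in enumerate(zip(scores, cnn_labels)):
        if rule == "any_accept":
            accept = bool(np.any(row <= tau))
        else:
            c = aes_task_order.index(cnn_label)
            accept = bool(row[c] <= tau[c])
        decisions.append(
            Decision(
                probe_id=i,
                predicted=cnn_label if accept else NOVEL,
                cnn_label=cnn_label,
                scores={t: float(s) for t, s in zip(aes_task_order, row)},
                rule=rule,
            )
        )
    return decisions


def decide(
    images,
    cnn: TrainedCNN,
    aes: AutoencoderSet,
    th: ThresholdTable,
    rule: str = "any_accept",
) -> list[Decision]:
    """End-to-end decision for feature image(s): a target-task label or NOVEL."""
    if aes.task_order != sorted(cnn.class_labels):
        raise ValueError("autoencoder task order does not match the classifier's classes")
    p = np.atleast_2d(predict_proba(cnn, images))
    cnn_labels = [cnn.class_labels[int(i)] for i in p.argmax(axis=1)]
    z = np.atleast_2d(embed(cnn, images))
    scores = score_matrix(aes, z)
    return decide_scores(scores, cnn_labels, aes.task_order, th, rule)
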