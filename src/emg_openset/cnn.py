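"""Convolutional classifier for electrode-grid feature images.

Architecture (four blocks):

* block 1 — two 3x3 convolutional layers, 32 filters each, ReLU, zero "same"
  padding so the 12 x 8 map keeps its extent;
* block 2 — dense (1024 by default) + ReLU + dropout;
* block 3 — dense 512 + ReLU + dropout; its post-activation output is the
  embedding handed to the novelty detectors;
* block 4 — dense M + softmax over the M target classes.

Trained with mini-batch AdaDelta on the mean cross-entropy, batch 16,
learning rate 0.05, 100 epochs by default.  Dropout "rate" is the drop
probability (0.8 by default); a keep-probability reading is available via
``dropout_is_keep_prob``.

Feature images are divided by per-feature-type (MAV/WL/RMS) training means
before entering the network — a conditioning step that preserves
nonnegativity; the divisors are stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import FeatureImage


@dataclass
class CnnSpec:
    input_shape: tuple[int, int, int] = (12, 8, 3)
    conv_filters: int = 32
    kernel_size: int = 3
    block2_width: int = 1024
    embed_width: int = 512
    n_classes: int = 7
    dropout_rate: float = 0.8
    dropout_is_keep_prob: bool = False
    padding: str = "same"
    # divide each image by its own mean so the network sees contraction-level
    # invariant spatial patterns (per-feature-type scaling is applied first)
    per_image_norm: bool = True

    @property
    def drop_prob(self) -> float:
        return 1.0 - self.dropout_rate if self.dropout_is_keep_prob else self.dropout_rate


@dataclass
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 0.05
    epochs: int = 100
    seed: int = 0
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6


@dataclass
class TrainedCNN:
    net: nn.Sequential
    spec: CnnSpec
    class_labels: list[str]
    feature_scale: np.ndarray  # (3,) per-feature-type divisors
    training_history: list[dict] = field(default_factory=list)

    # layer indices of the embedding tap (post-ReLU of block 3)
    _embed_tap: int = 0


def _build_net(spec: CnnSpec, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    h, w, c = spec.input_shape
    if spec.padding != "same":
        raise NotImplementedError("only zero 'same' padding is supported")
    drop = spec.drop_prob
    layers = [
        nn.Conv2DSame(c, spec.conv_filters, spec.kernel_size, rng),
        nn.ReLU(),
        nn.Conv2DSame(spec.conv_filters, spec.conv_filters, spec.kernel_size, rng),
        nn.ReLU(),
        nn.Flatten(),  # row-major (row, col, feature-map) order
        nn.Dense(h * w * spec.conv_filters, spec.block2_width, rng),
        nn.ReLU(),
        nn.Dropout(drop),
        nn.Dense(spec.block2_width, spec.embed_width, rng),
        nn.ReLU(),
        nn.Dropout(drop),
        nn.Dense(spec.embed_width, spec.n_classes, rng),
    ]
    embed_tap = 9  # index of block-3 ReLU
    return nn.Sequential(layers), embed_tap


def _as_array(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([im.values if isinstance(im, FeatureImage) else im for im in images])
    return arr.astype(np.float32)


def train_cnn(
    train_images,
    train_labels,
    val_images=None,
    val_labels=None,
    spec: CnnSpec | None = None,
    cfg: TrainConfig | None = None,
) -> TrainedCNN:
    """Train the classifier; deterministic for a fixed seed, single-threaded.

    Records per-epoch training loss/accuracy (and validation metrics when a
    validation set is given).  Raises on a single-class training set, on
    ``epochs < 1`` and on non-finite loss.
    """
    spec = spec or CnnSpec()
    cfg = cfg or TrainConfig()
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if cfg.batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    x = _as_array(train_images)
    labels = np.asarray(train_labels)
    class_labels = sorted(np.unique(labels).tolist())
    if len(class_labels) < 2:
        raise ValueError("training set must contain at least two classes")
    if len(class_labels) != spec.n_classes:
        spec = CnnSpec(**{**spec.__dict__, "n_classes": len(class_labels)})
    label_to_idx = {c: i for i, c in enumerate(class_labels)}
    y = np.array([label_to_idx[l] for l in labels])

    scale = x.reshape(-1, x.shape[-1]).mean(axis=0)
    scale = np.where(scale > 0, scale, 1.0).astype(np.float32)
    x = _condition(x / scale, spec)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    net, tap = _build_net(spec, rng)
    head = nn.SoftmaxCrossEntropy()
    opt = nn.AdaDelta(cfg.learning_rate, cfg.adadelta_rho, cfg.adadelta_eps)

    have_val = val_images is not None and len(val_images) > 0
    if have_val:
        xv = _condition(_as_array(val_images) / scale, spec)
        yv = np.array([label_to_idx[l] for l in np.asarray(val_labels)])

    history = []
    model = TrainedCNN(net, spec, class_labels, scale, history, tap)
    for epoch in range(cfg.epochs):
        losses = []
        correct = 0
        for batch in nn.minibatches(len(x), cfg.batch_size, rng):
            logits = net.forward(x[batch], train=True, rng=rng)
            loss, grad = head.loss_and_grad(logits, y[batch])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step(net.params, net.grads)
            losses.append(loss)
            correct += int(np.sum(logits.argmax(axis=1) == y[batch]))
        # running training accuracy, accumulated over the epoch's batches
        record = {"epoch": epoch, "loss": float(np.mean(losses)),
                  "accuracy": correct / len(x)}
        if have_val:
            logits_v = _forward_logits(model, xv, scaled=True)
            pv = nn.softmax(logits_v)
            record["val_loss"] = float(
                np.mean(-np.log(np.clip(pv[np.arange(len(yv)), yv], nn.EPS_LOG, None)))
            )
            record["val_accuracy"] = float(np.mean(logits_v.argmax(axis=1) == yv))
        history.append(record)
    return model


def _condition(x: np.ndarray, spec: CnnSpec) -> np.ndarray:
    """Optional per-image mean normalization (contraction-level invariance)."""
    if not spec.per_image_norm:
        return x
    m = x.mean(axis=(1, 2, 3), keepdims=True)
    return (x / np.where(m > 0, m, 1.0)).astype(np.float32)


def _forward_logits(model: TrainedCNN, x: np.ndarray, scaled: bool = False) -> np.ndarray:
    if not scaled:
        x = _condition(_as_array(x) / model.feature_scale, model.spec)
    return model.net.forward(x.astype(np.float32), train=False)


def predict_proba(model: TrainedCNN, images) -> np.ndarray:
    """Class probabilities (rows sum to 1); dropout disabled at inference.

    Accepts a single FeatureImage / array or a batch; returns (n, M) or (M,).
    """
    single = isinstance(images, FeatureImage) or (
        isinstance(images, np.ndarray) and images.ndim == 3
    )
    x = _as_array([images] if single else images)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(f"image shape {x.shape[1:]} != spec {model.spec.input_shape}")
    p = nn.softmax(_forward_logits(model, x))
    return p[0] if single else p


def predict_label(model: TrainedCNN, images):
    p = predict_proba(model, images)
    idx = np.argmax(p, axis=-1)
    if np.ndim(idx) == 0:
        return model.class_labels[int(idx)]
    return [model.class_labels[i] for i in idx]


def embed(model: TrainedCNN, images) -> np.ndarray:
    """Block-3 post-activation embedding (length 512, entries >= 0)."""
    single = isinstance(images, FeatureImage) or (
        isinstance(images, np.ndarray) and images.ndim == 3
    )
    x = _as_array([images] if single else images)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(f"image shape {x.shape[1:]} != spec {model.spec.input_shape}")
    x = _condition((x / model.feature_scale).astype(np.float32), model.spec)
    out = x
    for layer in model.net.layers[: model._embed_tap + 1]:
        out = layer.forward(out, train=False)
    return out[0] if single else out
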