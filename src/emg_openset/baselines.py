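"""Conventional pattern-recognition baselines.

* LDA: the classic time-domain pipeline — four Hudgins-style features per
  channel (MAV, WL, zero crossings, slope-sign changes), concatenated into a
  384-long vector for 96 channels, classified by linear discriminant analysis.
  It is closed-set: every probe gets one of the trained labels, never NOVEL.
* LDA-MD: the same classifier cascaded with a Mahalanobis-distance rejection
  stage.  Probes are projected into the discriminant space (rank <= M-1); the
  anomaly score is the Mahalanobis distance, under the pooled within-class
  covariance of the projected training data, to the predicted class centroid.
  Thresholds come from the same recall-factor calibration as the autoencoder
  detector.

The discriminant fit is delegated to scikit-learn (eigen solver with
shrinkage); the Mahalanobis scoring and rejection cascade are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .novelty import NOVEL, Decision, ThresholdTable
from .preprocessing import Window

TD4_ORDER = ("MAV", "WL", "ZC", "SSC")


def td4_features(w: Window | np.ndarray, eps: float | np.ndarray = 0.0) -> np.ndarray:
    """Four time-domain features per channel, concatenated channel-major.

    Per channel: mean absolute value, waveform length, zero-crossing count
    (sign change with both samples above the deadzone ``eps``) and slope-sign
    change count (slope reversal with at least one slope above ``eps``).
    ``eps`` may be a scalar or per-channel vector.
    """
    data = np.asarray(w.data if isinstance(w, Window) else w, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 1:
        raise ValueError("window must be a nonempty channels x samples array")
    eps_col = np.broadcast_to(np.asarray(eps, dtype=float), (data.shape[0],))[:, None]
    mav = np.mean(np.abs(data), axis=1)
    wl = np.sum(np.abs(np.diff(data, axis=1)), axis=1)
    a, b = data[:, :-1], data[:, 1:]
    zc = np.sum(
        (a * b < 0) & (np.abs(a) > eps_col) & (np.abs(b) > eps_col), axis=1
    ).astype(float)
    if data.shape[1] >= 3:
        d1 = data[:, 1:-1] - data[:, :-2]
        d2 = data[:, 1:-1] - data[:, 2:]
        ssc = np.sum(
            (d1 * d2 > 0) & ((np.abs(d1) > eps_col) | (np.abs(d2) > eps_col)), axis=1
        ).astype(float)
    else:
        ssc = np.zeros(data.shape[0])
    return np.stack([mav, wl, zc, ssc], axis=1).ravel()


def td4_matrix(windows: list[Window], eps=0.0) -> np.ndarray:
    return np.stack([td4_features(w, eps) for w in windows])


def fit_deadzone(windows: list[Window], factor: float = 0.01) -> np.ndarray:
    """Per-channel ZC/SSC deadzone: ``factor`` times the training-set SD."""
    stacked = np.concatenate([np.asarray(w.data, dtype=np.float64) for w in windows], axis=1)
    return factor * stacked.std(axis=1)


@dataclass
class LdaModel:
    """Fitted discriminant model plus the projected-space geometry for MD."""

    clf: LinearDiscriminantAnalysis
    class_labels: list[str]
    proj_means: np.ndarray  # (M, d) class centroids in discriminant space
    proj_cov: np.ndarray  # (d, d) pooled within-class covariance, projected
    shrinkage: float
    _cov_chol: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def project(self, x: np.ndarray) -> np.ndarray:
        return self.clf.transform(np.atleast_2d(np.asarray(x, dtype=float)))


def lda_fit(x: np.ndarray, y, shrinkage: float = 1e-3) -> LdaModel:
    """Fit the LDA baseline with Ledoit-style shrinkage of the 384-dim covariance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) < 2:
        raise ValueError("LDA needs at least two classes")
    clf = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage if shrinkage == "auto" or shrinkage > 0 else None
    )
    try:
        clf.fit(x, y)
    except np.linalg.LinAlgError as err:  # pragma: no cover - depends on data rank
        raise np.linalg.LinAlgError(
            "singular within-class covariance; refit with shrinkage > 0"
        ) from err
    z = clf.transform(x)
    means = np.stack([z[y == c].mean(axis=0) for c in clf.classes_])
    centered = z - means[np.searchsorted(clf.classes_, y)]
    dof = max(len(z) - len(labels), 1)
    cov = centered.T @ centered / dof
    cov += 1e-9 * np.eye(cov.shape[0])  # numerical floor
    chol = linalg.cholesky(cov, lower=True)
    return LdaModel(clf, list(clf.classes_), means, cov, shrinkage, chol)


def lda_predict(m: LdaModel, x: np.ndarray):
    """Closed-set prediction: always one of the trained labels."""
    pred = m.clf.predict(np.atleast_2d(np.asarray(x, dtype=float)))
    return pred if np.asarray(x).ndim > 1 else pred[0]


def mahalanobis(z: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """sqrt((z - mu)^T cov^-1 (z - mu)) for row(s) ``z``."""
    diff = np.atleast_2d(z) - mu
    sol = linalg.solve(cov, diff.T, assume_a="pos")
    return np.sqrt(np.einsum("ij,ji->i", diff, sol))


@dataclass
class MdScore:
    predicted: str
    score: float  # MD to the predicted class centroid
    all_distances: dict[str, float]


def lda_md_score(m: LdaModel, x: np.ndarray, mode: str = "predicted") -> list[MdScore]:
    """Mahalanobis anomaly scores in the discriminant-projected space.

    ``mode='predicted'`` (default) scores the distance to the LDA-predicted
    class centroid; ``mode='min'`` scores the minimum distance over classes.
    """
    if mode not in ("predicted", "min"):
        raise ValueError("mode must be 'predicted' or 'min'")
    z = m.project(x)
    pred = m.clf.predict(np.atleast_2d(np.asarray(x, dtype=float)))
    dists = np.stack(
        [mahalanobis(z, mu, m.proj_cov) for mu in m.proj_means], axis=1
    )  # (n, M)
    out = []
    for i, p in enumerate(pred):
        all_d = {c: float(d) for c, d in zip(m.class_labels, dists[i])}
        score = min(all_d.values()) if mode == "min" else all_d[p]
        out.append(MdScore(predicted=p, score=score, all_distances=all_d))
    return out


def lda_md_decide(
    m: LdaModel, th: ThresholdTable, x: np.ndarray, mode: str = "predicted"
) -> list[Decision]:
    """Accept a probe iff its MD to the predicted centroid is within threshold."""
    missing = [c for c in m.class_labels if c not in th.thresholds]
    if missing:
        raise ValueError(f"missing thresholds for classes {missing}")
    decisions = []
    for i, s in enumerate(lda_md_score(m, x, mode=mode)):
        accept = s.score <= th.thresholds[s.predicted]
        decisions.append(
            Decision(
                probe_id=i,
                predicted=s.predicted if accept else NOVEL,
                cnn_label=s.predicted,
                scores=s.all_distances,
                rule="predicted_class",
            )
        )
    return decisions
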