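"""End-to-end experiment orchestration.

``run_experiment`` drives simulate -> preprocess -> train CNN -> train
autoencoders -> calibrate thresholds -> baselines -> evaluate as one seeded,
reproducible run, per subject, and writes a report bundle (models, thresholds,
accuracy tables, ROC points, manifest) under one output directory.

Every stage seed is derived from the single master seed; the manifest records
all of them.  With ``resume=True`` stages whose artifacts already exist on
disk are reloaded instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .baselines import fit_deadzone, lda_fit, lda_md_decide, lda_md_score, lda_predict, td4_matrix
from .cnn import CnnSpec, TrainConfig, embed, predict_proba, train_cnn
from .evaluation import (
    DEFAULT_R_GRID,
    accuracy_from_confusion,
    confusion,
    motion_accuracy,
    roc_sweep,
)
from .grids import GridSpec
from .novelty import (
    NOVEL,
    AutoencoderSpec,
    Decision,
    calibrate_thresholds,
    decide_scores,
    score_matrix,
    train_autoencoders,
)
from .preprocessing import (
    DEFAULT_FRACTIONS,
    feature_image,
    fit_activity_threshold,
    gate_windows,
    segment_windows,
    split_dataset,
)
from .synthetic import (
    BenchmarkConfig,
    NOVEL_TASKS,
    STATIC_NOVEL_TASKS,
    DYNAMIC_NOVEL_TASKS,
    TARGET_TASKS,
    make_benchmark,
)

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One experiment: study conditions plus every model hyperparameter.

    The defaults are the documented preset: 250/150 ms windows, 12x8x3 images,
    64/16/20 split, 32 3x3 filters, 512-wide embedding, dropout 0.8, batch 16,
    AdaDelta at 0.05 for 100 epochs, autoencoder SGD at 0.1/0.01 over 600+300
    epochs, recall factor 0.85 with the any-accept rule.  Values that are
    protocol-specific rather than externally prescribed (the synthetic
    benchmark's subject count, noise levels, LDA shrinkage, ZC/SSC deadzone)
    are plain config fields like everything else.
    """

    seed: int = 0
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    win_ms: float = 250.0
    inc_ms: float = 150.0
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    cnn_spec: CnnSpec = field(default_factory=CnnSpec)
    cnn_train: TrainConfig = field(default_factory=TrainConfig)
    ae_spec: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    recall_factor: float = 0.85
    decision_rule: str = "any_accept"
    lda_shrinkage: float = 1e-3
    deadzone_factor: float = 0.01
    n_roc_points: int = 101

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "benchmark" in d and isinstance(d["benchmark"], dict):
            b = dict(d["benchmark"])
            if isinstance(b.get("grid"), dict):
                g = {k: v for k, v in b["grid"].items() if k != "channel_order"}
                b["grid"] = GridSpec(**g)
            for key in ("rep_gain_jitter", "switch_interval_s", "knot_gain_range"):
                if b.get(key) is not None:
                    b[key] = tuple(b[key])
            d["benchmark"] = BenchmarkConfig(**b)
        if "cnn_spec" in d and isinstance(d["cnn_spec"], dict):
            s = dict(d["cnn_spec"])
            s["input_shape"] = tuple(s["input_shape"])
            d["cnn_spec"] = CnnSpec(**s)
        if "cnn_train" in d and isinstance(d["cnn_train"], dict):
            d["cnn_train"] = TrainConfig(**d["cnn_train"])
        if "ae_spec" in d and isinstance(d["ae_spec"], dict):
            s = dict(d["ae_spec"])
            s["layer_widths"] = tuple(s["layer_widths"])
            s["lr_schedule"] = tuple(tuple(x) for x in s["lr_schedule"])
            d["ae_spec"] = AutoencoderSpec(**s)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items() if k != "channel_order"}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Structured list of configuration contradictions (empty when valid)."""
    errors = []
    if abs(sum(cfg.fractions) - 1.0) > 1e-9 or len(cfg.fractions) != 3:
        errors.append(f"split fractions {cfg.fractions} must be three numbers summing to 1")
    if not 0.0 <= cfg.recall_factor <= 1.0:
        errors.append(f"recall factor {cfg.recall_factor} outside [0, 1]")
    if cfg.decision_rule not in ("any_accept", "predicted_class"):
        errors.append(f"unknown decision rule {cfg.decision_rule!r}")
    if cfg.win_ms > cfg.benchmark.rep_duration_s * 1000.0:
        errors.append("analysis window longer than one repetition")
    if cfg.inc_ms <= 0 or cfg.win_ms <= 0:
        errors.append("window length and increment must be positive")
    w = cfg.ae_spec.layer_widths
    if min(w) >= w[0]:
        errors.append("autoencoder bottleneck must be narrower than the embedding")
    if w[0] != cfg.cnn_spec.embed_width:
        errors.append("autoencoder input width must equal the CNN embedding width")
    if cfg.cnn_train.epochs < 1:
        errors.append("CNN epochs must be >= 1")
    if cfg.benchmark.n_subjects < 1:
        errors.append("need at least one subject")
    return errors


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(recordings, win_ms=250.0, inc_ms=150.0):
    """Gate and featurize one subject's recordings.

    Returns ``(images, windows, meta)``: stacked feature-image values, the
    gated Window objects (for time-domain baselines) and a metadata frame
    (task, kind, rep, start).
    """
    baselines = [r for r in recordings if r.baseline]
    if not baselines:
        raise ValueError("subject has no baseline recording to fit the activity gate")
    thr = fit_activity_threshold(baselines[0])
    grid = recordings[0].grid
    images, windows, meta = [], [], []
    for rec in recordings:
        if rec.baseline:
            continue
        for w in gate_windows(segment_windows(rec, win_ms, inc_ms), thr):
            img = feature_image(w, grid)
            images.append(img.values)
            windows.append(w)
            kind = "target" if rec.task_id in TARGET_TASKS else (
                "static_novel" if rec.task_id in STATIC_NOVEL_TASKS else "dynamic_novel"
            )
            meta.append(dict(task=rec.task_id, kind=kind, rep=rec.rep_index, start=w.source[2]))
    return np.stack(images), windows, pd.DataFrame(meta), thr


# ---------------------------------------------------------------------------
# per-subject experiment
# ---------------------------------------------------------------------------

def _subject_seed(master: int, subject: int, salt: int) -> int:
    return int(np.random.SeedSequence([master, subject, salt]).generate_state(1)[0] % (2**31))


def run_subject(
    recordings, cfg: ExperimentConfig, subject: int, out_dir: Path | None = None,
    resume: bool = False,
) -> dict:
    """Run the full method and both baselines for one subject's recordings."""
    t0 = time.time()
    images, windows, meta, thr = extract_features(recordings, cfg.win_ms, cfg.inc_ms)
    labels = meta["task"].to_numpy()
    is_target = (meta["kind"] == "target").to_numpy()
    target_idx = np.flatnonzero(is_target)
    novel_idx = np.flatnonzero(~is_target)

    split = split_dataset(
        labels[target_idx], cfg.fractions, seed=_subject_seed(cfg.seed, subject, 1)
    )
    tr, va, te = (target_idx[s] for s in (split.train, split.validation, split.test))
    logger.info(
        "subject %d: %d target windows (%d/%d/%d), %d novel windows",
        subject, len(target_idx), len(tr), len(va), len(te), len(novel_idx),
    )

    # ----- CNN ---------------------------------------------------------
    cnn_path = out_dir / f"s{subject}_cnn.npz" if out_dir else None
    if resume and cnn_path and cnn_path.exists():
        model = eio.load_cnn(cnn_path)
    else:
        cnn_cfg = dataclasses.replace(cfg.cnn_train, seed=_subject_seed(cfg.seed, subject, 2))
        model = train_cnn(images[tr], labels[tr], images[va], labels[va], cfg.cnn_spec, cnn_cfg)
        if cnn_path:
            eio.save_cnn(cnn_path, model)
    test_proba = predict_proba(model, images[te])
    cnn_test_pred = np.array([model.class_labels[i] for i in test_proba.argmax(axis=1)])
    cnn_test_acc = float(np.mean(cnn_test_pred == labels[te]))

    # ----- autoencoders ------------------------------------------------
    z_train = embed(model, images[tr])
    ae_path = out_dir / f"s{subject}_aes.npz" if out_dir else None
    if resume and ae_path and ae_path.exists():
        aes = eio.load_autoencoders(ae_path)
    else:
        ae_spec = dataclasses.replace(cfg.ae_spec, seed=_subject_seed(cfg.seed, subject, 3))
        groups = {t: z_train[labels[tr] == t] for t in model.class_labels}
        aes = train_autoencoders(groups, ae_spec)
        if ae_path:
            eio.save_autoencoders(ae_path, aes)

    # ----- calibration -------------------------------------------------
    z_val = embed(model, images[va])
    val_scores = score_matrix(aes, z_val)
    cal_scores = {
        t: val_scores[labels[va] == t, aes.task_order.index(t)] for t in aes.task_order
    }
    th = calibrate_thresholds(cal_scores, cfg.recall_factor)
    if out_dir:
        eio.save_thresholds(out_dir / f"s{subject}_thresholds.json", th)

    # ----- proposed method on the test stream --------------------------
    eval_idx = np.concatenate([te, novel_idx])
    z_eval = embed(model, images[eval_idx])
    eval_scores = score_matrix(aes, z_eval)
    p_eval = predict_proba(model, images[eval_idx])
    eval_cnn_labels = [model.class_labels[i] for i in p_eval.argmax(axis=1)]
    ae_decisions = decide_scores(eval_scores, eval_cnn_labels, aes.task_order, th, cfg.decision_rule)
    truth = labels[eval_idx]
    targets = list(model.class_labels)
    ae_acc = motion_accuracy(ae_decisions, truth, targets)
    ae_conf = confusion(ae_decisions, truth, targets, list(NOVEL_TASKS))
    ae_roc = roc_sweep(
        cal_scores,
        eval_scores[: len(te)],
        eval_scores[len(te):],
        aes.task_order,
        np.linspace(0, 1, cfg.n_roc_points),
    )

    # ----- LDA / LDA-MD baselines --------------------------------------
    eps = fit_deadzone([windows[i] for i in tr], cfg.deadzone_factor)
    td = td4_matrix(windows, eps)
    lda = lda_fit(td[tr], labels[tr], cfg.lda_shrinkage)
    lda_pred = lda_predict(lda, td[eval_idx])
    lda_decisions = [
        Decision(i, p, p, {}, rule="predicted_class") for i, p in enumerate(lda_pred)
    ]
    lda_acc = motion_accuracy(lda_decisions, truth, targets)
    lda_conf = confusion(lda_decisions, truth, targets, list(NOVEL_TASKS))

    md_val = lda_md_score(lda, td[va])
    md_cal = {
        t: np.array([s.score for s, l in zip(md_val, labels[va]) if l == t])
        for t in lda.class_labels
    }
    md_th = calibrate_thresholds(md_cal, cfg.recall_factor)
    md_decisions = lda_md_decide(lda, md_th, td[eval_idx])
    md_acc = motion_accuracy(md_decisions, truth, targets)
    md_conf = confusion(md_decisions, truth, targets, list(NOVEL_TASKS))
    md_eval = lda_md_score(lda, td[eval_idx])
    md_matrix = np.full((len(eval_idx), len(lda.class_labels)), np.inf)
    for i, s in enumerate(md_eval):
        md_matrix[i, lda.class_labels.index(s.predicted)] = s.score
    md_roc = roc_sweep(
        md_cal,
        md_matrix[: len(te)],
        md_matrix[len(te):],
        lda.class_labels,
        np.linspace(0, 1, cfg.n_roc_points),
    )

    # Per-task anomaly-score separation on the evaluation stream: for each
    # target task k, the median score of its own held-out samples under its
    # autoencoder versus the median score of every other sample.
    separation = {}
    for k, task in enumerate(aes.task_order):
        own = eval_scores[truth == task, k]
        other = eval_scores[truth != task, k]
        separation[task] = {
            "own_median": float(np.median(own)),
            "other_median": float(np.median(other)),
        }

    result = {
        "subject": subject,
        "n_windows": {"target": int(len(target_idx)), "novel": int(len(novel_idx))},
        "score_separation": separation,
        "cnn_test_accuracy": cnn_test_acc,
        "auc": {"proposed": ae_roc.auc, "lda_md": md_roc.auc},
        "accuracy": {"proposed": ae_acc, "lda_md": md_acc, "lda": lda_acc},
        "confusion": {
            "proposed": ae_conf.to_dict(),
            "lda_md": md_conf.to_dict(),
            "lda": lda_conf.to_dict(),
        },
        "roc_points": {"proposed": ae_roc.points, "lda_md": md_roc.points},
        "thresholds": th.thresholds,
        "wall_time_s": time.time() - t0,
    }
    # cross-check identity: per-motion accuracies from the confusion matrix
    for name, conf_mat, acc in (
        ("proposed", ae_conf, ae_acc), ("lda_md", md_conf, md_acc), ("lda", lda_conf, lda_acc)
    ):
        derived = accuracy_from_confusion(conf_mat, targets)
        for task, val in acc.items():
            assert abs(derived[task] - val) < 1e-12, (name, task)
    return result


def summarize(per_subject: list[dict]) -> dict:
    """Across-subject mean +/- SD of AUC and per-motion accuracies."""
    out: dict = {"n_subjects": len(per_subject)}
    for method in ("proposed", "lda_md"):
        vals = [r["auc"][method] for r in per_subject]
        out[f"auc_{method}"] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    for method in ("proposed", "lda_md", "lda"):
        tasks = sorted({t for r in per_subject for t in r["accuracy"][method]})
        out[f"accuracy_{method}"] = {
            t: {
                "mean": float(np.mean([r["accuracy"][method][t] for r in per_subject])),
                "sd": float(np.std([r["accuracy"][method][t] for r in per_subject])),
            }
            for t in tasks
        }
    return out


def accuracy_table(per_subject: list[dict]) -> pd.DataFrame:
    """Methods x motions table of mean accuracies (%): target average first,
    then each novel motion, mirroring the standard open-set report layout."""
    rows = {}
    for method, label in (("lda", "LDA"), ("lda_md", "LDA-MD"), ("proposed", "Proposed")):
        accs = {}
        target_vals = []
        for r in per_subject:
            for t, v in r["accuracy"][method].items():
                accs.setdefault(t, []).append(v)
        row = {}
        for t, vals in sorted(accs.items()):
            if t in TARGET_TASKS:
                target_vals.extend(vals)
            else:
                row[t] = 100.0 * float(np.mean(vals))
        row = {"target_avg": 100.0 * float(np.mean(target_vals)), **row}
        rows[label] = row
    return pd.DataFrame(rows).T


def run_experiment(
    cfg: ExperimentConfig | None = None,
    out_dir=None,
    resume: bool = False,
) -> dict:
    """Run the configured experiment end to end; returns the report dict.

    When ``out_dir`` is given, writes models, thresholds, the accuracy table
    (CSV), ROC points (CSV), the full report (JSON) and a manifest of derived
    seeds.
    """
    cfg = cfg or ExperimentConfig()
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_path / "config.yaml")
    report_file = out_path / "report.json" if out_path else None
    if resume and report_file and report_file.exists():
        return json.loads(report_file.read_text())

    sim_seed = _subject_seed(cfg.seed, 0, 0)
    recordings = make_benchmark(cfg.benchmark, rng_seed=sim_seed)
    per_subject = []
    for subject in range(cfg.benchmark.n_subjects):
        subject_recs = [r for r in recordings if r.subject == subject]
        per_subject.append(run_subject(subject_recs, cfg, subject, out_path, resume))
        logger.info("subject %d done in %.1f s", subject, per_subject[-1]["wall_time_s"])

    report = {
        "config_seed": cfg.seed,
        "derived_seeds": {
            "simulate": sim_seed,
            "splits": [_subject_seed(cfg.seed, s, 1) for s in range(cfg.benchmark.n_subjects)],
            "cnn": [_subject_seed(cfg.seed, s, 2) for s in range(cfg.benchmark.n_subjects)],
            "ae": [_subject_seed(cfg.seed, s, 3) for s in range(cfg.benchmark.n_subjects)],
        },
        "per_subject": per_subject,
        "summary": summarize(per_subject),
    }
    if out_path:
        accuracy_table(per_subject).to_csv(out_path / "accuracy_table.csv")
        roc_rows = [
            dict(subject=r["subject"], method=m, fpr=p[0], tpr=p[1])
            for r in per_subject
            for m in ("proposed", "lda_md")
            for p in r["roc_points"][m]
        ]
        pd.DataFrame(roc_rows).to_csv(out_path / "roc_points.csv", index=False)
        report_file.write_text(json.dumps(report, indent=1))
    return report
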