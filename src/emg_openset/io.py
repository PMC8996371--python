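"""HDF5 / CSV / JSON persistence for datasets, models and thresholds."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cnn import CnnSpec, TrainedCNN, _build_net
from .grids import GridSpec
from .novelty import Autoencoder, AutoencoderSet, AutoencoderSpec, ThresholdTable, _build_autoencoder
from .synthetic import RawRecording


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recordings(path, recordings: list[RawRecording]) -> None:
    """One HDF5 group per recording (/signal plus attrs) and a CSV manifest."""
    path = Path(path)
    rows = []
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            g = f.create_group(f"rec{i:05d}")
            g.create_dataset("signal", data=rec.signal, compression="gzip", compression_opts=1)
            g.attrs.update(
                fs=rec.fs,
                task_id=rec.task_id,
                rep=rec.rep_index,
                subject=rec.subject,
                baseline=rec.baseline,
                rows=rec.grid.rows,
                cols=rec.grid.cols,
            )
            rows.append(
                dict(group=f"rec{i:05d}", task_id=rec.task_id, rep=rec.rep_index,
                     subject=rec.subject, baseline=rec.baseline, n_samples=rec.n_samples)
            )
    pd.DataFrame(rows).to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_recordings(path) -> list[RawRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            grid = GridSpec(rows=int(g.attrs["rows"]), cols=int(g.attrs["cols"]))
            out.append(
                RawRecording(
                    signal=g["signal"][...],
                    fs=float(g.attrs["fs"]),
                    grid=grid,
                    task_id=str(g.attrs["task_id"]),
                    rep_index=int(g.attrs["rep"]),
                    baseline=bool(g.attrs["baseline"]),
                    subject=int(g.attrs["subject"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def save_features(path, images: np.ndarray, td: np.ndarray, meta: pd.DataFrame) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images.astype(np.float32), compression="gzip", compression_opts=1)
        f.create_dataset("td", data=td, compression="gzip", compression_opts=1)
    meta.to_csv(path.with_suffix(".meta.csv"), index=False)


def load_features(path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        td = f["td"][...]
    meta = pd.read_csv(path.with_suffix(".meta.csv"))
    return images, td, meta


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_cnn(path, model: TrainedCNN) -> None:
    """Weights as .npz with a JSON sidecar (spec, labels, scale, history)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params)}
    np.savez(path, **arrays)
    sidecar = {
        "spec": model.spec.__dict__,
        "class_labels": model.class_labels,
        "feature_scale": model.feature_scale.tolist(),
        "training_history": model.training_history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_cnn(path) -> TrainedCNN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(sidecar["spec"])
    spec_d["input_shape"] = tuple(spec_d["input_shape"])
    spec = CnnSpec(**spec_d)
    net, tap = _build_net(spec, np.random.default_rng(0))
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, p in enumerate(net.params):
        p[...] = data[f"p{i}"]
    return TrainedCNN(
        net=net,
        spec=spec,
        class_labels=list(sidecar["class_labels"]),
        feature_scale=np.asarray(sidecar["feature_scale"], dtype=np.float32),
        training_history=sidecar["training_history"],
        _embed_tap=tap,
    )


def save_autoencoders(path, aes: AutoencoderSet) -> None:
    path = Path(path)
    arrays = {}
    spec = None
    for task, ae in aes.models.items():
        spec = ae.spec
        for i, p in enumerate(ae.net.params):
            arrays[f"{task}__p{i}"] = p
    np.savez(path, **arrays)
    sidecar = {
        "task_order": aes.task_order,
        "embed_scale": aes.embed_scale,
        "spec": {
            "layer_widths": list(spec.layer_widths),
            "batch_size": spec.batch_size,
            "lr_schedule": [list(s) for s in spec.lr_schedule],
            "max_grad_norm": spec.max_grad_norm,
            "seed": spec.seed,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_autoencoders(path) -> AutoencoderSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = AutoencoderSpec(
        layer_widths=tuple(sidecar["spec"]["layer_widths"]),
        batch_size=sidecar["spec"]["batch_size"],
        lr_schedule=tuple(tuple(s) for s in sidecar["spec"]["lr_schedule"]),
        max_grad_norm=sidecar["spec"].get("max_grad_norm", 5.0),
        seed=sidecar["spec"]["seed"],
    )
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    models: dict[str, Autoencoder] = {}
    for task in sidecar["task_order"]:
        ae = _build_autoencoder(spec, task, np.random.default_rng(0))
        for i, p in enumerate(ae.net.params):
            p[...] = data[f"{task}__p{i}"]
        models[task] = ae
    return AutoencoderSet(models, list(sidecar["task_order"]), float(sidecar["embed_scale"]))


def save_thresholds(path, th: ThresholdTable) -> None:
    Path(path).write_text(
        json.dumps({"recall_factor": th.recall_factor, "thresholds": th.thresholds}, indent=1)
    )


def load_thresholds(path) -> ThresholdTable:
    d = json.loads(Path(path).read_text())
    return ThresholdTable(float(d["recall_factor"]), {k: float(v) for k, v in d["thresholds"].items()})
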