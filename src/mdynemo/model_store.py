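"""HDF5 checkpoints for trained models (+ JSON config/loss metadata)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .core import PCAProjection
from .inference import TrainedModel, TrainingConfig

__all__ = ["save_model", "load_model"]


def _write_tree(group, tree: dict) -> None:
    for key, value in tree.items():
        if isinstance(value, dict):
            _write_tree(group.create_group(key), value)
        else:
            group.create_dataset(key, data=np.asarray(value))


def _read_tree(group) -> dict:
    out = {}
    for key, value in group.items():
        out[key] = _read_tree(value) if isinstance(value, h5py.Group) else value[()]
    return out


def save_model(path, model: TrainedModel) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_tree(f.create_group("params"), model.params)
        f.attrs["n_channels"] = model.n_channels
        f.attrs["single_dynamic"] = model.single_dynamic
        if model.pca is not None:
            f.create_dataset("pca/w", data=model.pca.w)
    meta = {
        "config": dataclasses.asdict(model.config),
        "loss_history": model.loss_history.tolist(),
        "restart_losses": model.restart_losses.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    with h5py.File(path, "r") as f:
        params = _read_tree(f["params"])
        n_channels = int(f.attrs["n_channels"])
        single = bool(f.attrs["single_dynamic"])
        pca = PCAProjection(w=f["pca/w"][()]) if "pca" in f else None
    meta_path = path.with_suffix(path.suffix + ".json")
    config = TrainingConfig()
    loss = np.zeros(0)
    restarts = np.zeros(0)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        config = TrainingConfig(**meta["config"])
        loss = np.asarray(meta["loss_history"])
        restarts = np.asarray(meta["restart_losses"])
    return TrainedModel(
        params=params,
        config=config,
        n_channels=n_channels,
        single_dynamic=single,
        pca=pca,
        loss_history=loss,
        restart_losses=restarts,
    )
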