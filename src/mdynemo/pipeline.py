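"""End-to-end pipeline: simulate → preprocess → train → infer → baseline → stats.

A :class:`RunConfig` (YAML-serialisable, lossless round-trip) drives the
whole run; the single top-level seed fans out to per-stage seeds through
a fixed spawn schedule so any stage can be reproduced in isolation. Every
output directory carries the config, the seed table and a version stamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import TrainingConfig, infer_mixing, train, train_single_dynamic
from .io import read_sessions, stage_seeds, write_sessions
from .postanalysis import coupling_matrix, renormalise
from .preprocess import PreprocessConfig, preprocess_sessions
from .simulate import SimConfig, simulate
from .sliding_window import kmeans_states, state_tc_correlation, window_features

log = logging.getLogger("mdynemo")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SlidingWindowConfig:
    window: int = 500
    step: int = 10
    n_states: int = 4
    n_restarts: int = 10


@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    seed: int = 0
    output_dir: str = "mdynemo-run"
    data_path: str | None = None  # None -> simulate
    simulation: SimConfig = field(default_factory=SimConfig)
    preprocessing: PreprocessConfig | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    train_single: bool = False
    sliding_window: SlidingWindowConfig = field(default_factory=SlidingWindowConfig)
    n_perm: int = 1000

    _SECTIONS = {
        "simulation": SimConfig,
        "preprocessing": PreprocessConfig,
        "training": TrainingConfig,
        "sliding_window": SlidingWindowConfig,
    }

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["simulation"].get("task") is not None:
            task = d["simulation"]["task"]
            d["simulation"]["task"] = task if isinstance(task, list) else [task]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for name, typ in cls._SECTIONS.items():
            if isinstance(d.get(name), dict):
                section = dict(d[name])
                extra = {k for k in section if k not in {f.name for f in dataclasses.fields(typ)}}
                if extra:
                    raise ValueError(f"unknown config key(s) in {name}: {sorted(extra)}")
                if name == "simulation" and section.get("task"):
                    from .simulate import TaskConfig

                    section["task"] = [TaskConfig(**t) for t in section["task"]]
                d[name] = typ(**section)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artefact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    seeds = stage_seeds(config.seed)
    config.to_yaml(out / "config.yaml")
    (out / "meta.json").write_text(
        json.dumps(
            {"version": __version__, "config_hash": _config_hash(config), "seeds": seeds},
            indent=2,
        )
    )
    try:
        return _run_stages(config, out, seeds)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path, seeds: dict) -> Path:
    def stage(name, fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as err:  # annotate and halt
            log.error("stage %s: FAILED (%s)", name, err)
            raise PipelineError(name, err) from err
        log.info("stage %s: done", name)
        return result

    if config.data_path is not None:
        sessions = stage("load", read_sessions, config.data_path)
        truth = None
    else:
        sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        sessions, truth = stage("simulate", simulate, sim)
        stage("write-data", write_sessions, out / "sessions.h5", sessions)

    if config.preprocessing is not None:
        def _prep():
            return preprocess_sessions(sessions, config.preprocessing)

        sessions_p, pca = stage("preprocess", _prep)
    else:
        sessions_p, pca = sessions, None

    tc = dataclasses.replace(config.training, seed=seeds["train"])
    model = stage("train", train, sessions_p, tc, pca)
    np.save(out / "loss_history.npy", model.loss_history)
    from .core import save_mode_sets

    stage(
        "write-modes",
        save_mode_sets,
        out / "modes.h5",
        model.power_modes,
        model.fc_modes,
        sessions_p[0].channel_names,
    )

    if config.train_single:
        tc1 = dataclasses.replace(
            config.training, seed=seeds["train_single"], n_fc_modes=config.training.n_power_modes
        )
        model_single = stage("train-single", train_single_dynamic, sessions_p, tc1, pca)
        np.save(out / "loss_history_single.npy", model_single.loss_history)

    mixing = stage("infer", infer_mixing, model, sessions_p)
    alphas = [renormalise(m.alpha, model.power_modes) for m in mixing]
    betas = [renormalise(m.beta, model.fc_modes) for m in mixing]
    for i, (a, b) in enumerate(zip(alphas, betas)):
        pd.DataFrame(a).to_csv(out / f"alpha_session{i}.csv", index=False)
        pd.DataFrame(b).to_csv(out / f"beta_session{i}.csv", index=False)

    def _sliding():
        sw = config.sliding_window
        rows = []
        for i, s in enumerate(sessions_p):
            feats = window_features(s.timeseries, sw.window, sw.step)
            pw, _ = kmeans_states(feats.stds, sw.n_states, seeds["sliding_window"], sw.n_restarts)
            fc, _ = kmeans_states(
                feats.correlations, sw.n_states, seeds["sliding_window"], sw.n_restarts
            )
            rows.append(
                pd.DataFrame(
                    {"session": i, "center": feats.centers, "power_state": pw, "fc_state": fc}
                )
            )
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "sliding_window_states.csv", index=False)
        first = rows[0]
        corr = state_tc_correlation(
            first["power_state"].to_numpy(), first["fc_state"].to_numpy()
        )
        pd.DataFrame(corr).to_csv(out / "sliding_window_state_correlation.csv", index=False)

    if all(s.n_samples >= config.sliding_window.window for s in sessions_p):
        stage("sliding-window", _sliding)

    def _coupling():
        r, res = coupling_matrix(
            [m.alpha for m in mixing],
            [m.beta for m in mixing],
            n_perm=config.n_perm,
            seed=seeds["postanalysis"],
        )
        payload = {
            "mean_z": res.observed.tolist(),
            "pvalues": res.pvalues.tolist(),
            "significant": res.mask.tolist(),
            "session_r": r.tolist(),
        }
        (out / "coupling.json").write_text(json.dumps(payload, indent=2))

    if len(sessions_p) >= 2:
        stage("coupling", _coupling)
    return out
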