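"""Session containers, HDF5/CSV readers and writers, and seed plumbing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SessionData",
    "read_sessions",
    "write_sessions",
    "read_events",
    "write_events",
    "stage_seeds",
]


@dataclass
class SessionData:
    """One recording session: a channels × time matrix plus metadata."""

    id: str
    x: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] == 0:
            raise ValueError("x must be a non-empty (n_channels, n_samples) matrix")
        if not np.all(np.isfinite(self.x)):
            raise ValueError(f"session {self.id!r} contains non-finite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.x.shape[0])]
        if len(self.channel_names) != self.x.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def timeseries(self) -> np.ndarray:
        """Time-major view ``(n_samples, n_channels)`` used by the models."""
        return self.x.T

    def with_timeseries(self, ts: np.ndarray) -> "SessionData":
        """Copy of this session with a replacement time-major matrix."""
        return SessionData(
            id=self.id,
            x=np.asarray(ts).T,
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
        )


def write_sessions(path, sessions: list[SessionData]) -> None:
    """Write sessions to an HDF5 store (``/sessions/<id>/x`` + attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        for s in sessions:
            g = f.create_group(f"sessions/{s.id}")
            g.create_dataset("x", data=s.x)
            g.attrs["sampling_rate"] = s.sampling_rate
            g.attrs["channel_names"] = [str(c) for c in s.channel_names]


def _read_sessions_hdf5(path) -> list[SessionData]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for sid in f["sessions"]:
            g = f[f"sessions/{sid}"]
            if "sampling_rate" not in g.attrs:
                raise ValueError(f"session {sid!r} is missing the sampling_rate attribute")
            out.append(
                SessionData(
                    id=sid,
                    x=g["x"][()],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    channel_names=[str(c) for c in g.attrs["channel_names"]],
                )
            )
    return out


def _read_sessions_csv_dir(path: Path) -> list[SessionData]:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {path}")
    table = pd.read_csv(manifest)
    out = []
    for row in table.itertuples():
        f = path / row.file
        if not f.exists():
            raise FileNotFoundError(f"manifest entry {row.file!r} not found in {path}")
        frame = pd.read_csv(f)
        out.append(
            SessionData(
                id=str(row.id),
                x=frame.to_numpy().T,
                sampling_rate=float(row.sampling_rate),
                channel_names=list(frame.columns),
            )
        )
    return out


def read_sessions(path) -> list[SessionData]:
    """Read sessions from an HDF5 store or a CSV directory with a manifest.

    CSV sessions are one file per session, channels as columns, listed in
    ``manifest.csv`` (columns: id, file, sampling_rate).
    """
    path = Path(path)
    if path.is_dir():
        sessions = _read_sessions_csv_dir(path)
    else:
        sessions = _read_sessions_hdf5(path)
    ncs = {s.n_channels for s in sessions}
    if len(ncs) > 1:
        raise ValueError(f"sessions have ragged channel counts: {sorted(ncs)}")
    return sessions


def write_events(path, events: pd.DataFrame) -> None:
    events[["onset_sample", "condition"]].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = {"onset_sample", "condition"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events


#: pipeline stages in fixed fan-out order
_STAGES = (
    "simulate",
    "preprocess",
    "train",
    "train_single",
    "infer",
    "sliding_window",
    "postanalysis",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single seed out to per-stage seeds via a fixed spawn schedule."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }
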