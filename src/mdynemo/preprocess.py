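"""Envelope preprocessing: band-pass, Hilbert envelope, smoothing, z-scoring, PCA.

The fixed stage order is band-pass filter → amplitude envelope → moving
average → per-session standardisation → full-rank group PCA; every stage
is optional via :class:`PreprocessConfig` but the order never changes.
The defaults reproduce the envelope pipeline used for 250 Hz parcel data:
1–45 Hz pass band and a 25-sample (100 ms) smoothing window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import PCAProjection
from .io import SessionData

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "amplitude_envelope",
    "moving_average",
    "standardise",
    "fit_apply_pca",
    "preprocess_sessions",
]


@dataclass
class PreprocessConfig:
    band: tuple[float, float] | None = (1.0, 45.0)
    envelope: bool = True
    smoothing_window: int = 25
    standardise: bool = True
    pca: bool = False
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.band is not None:
            low, high = self.band
            if not (0 < low < high < self.sampling_rate / 2):
                raise ValueError(
                    f"band {self.band} invalid for Nyquist {self.sampling_rate / 2} Hz"
                )
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")


def bandpass(x: np.ndarray, low: float, high: float, sampling_rate: float) -> np.ndarray:
    """Zero-phase 5th-order Butterworth band-pass along the time axis.

    ``x`` is time-major ``(T, Nc)``. Forward–backward application
    (``sosfiltfilt``) cancels phase delay, so envelope timing downstream is
    unaffected by the filter.
    """
    nyq = sampling_rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(5, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert-transformed) signal, per channel."""
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    return np.abs(signal.hilbert(x, axis=0))


def moving_average(x: np.ndarray, window: int = 25, step: int = 1) -> np.ndarray:
    """Trailing-edge-trimmed moving average: output length T − window + 1."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < window:
        raise ValueError(f"need at least {window} samples, got {x.shape[0]}")
    c = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x], axis=0), axis=0)
    out = (c[window:] - c[:-window]) / window
    return out[::step]


def standardise(x: np.ndarray) -> np.ndarray:
    """Per-channel z-transform (zero mean, unit variance) within a session."""
    sd = np.std(x, axis=0)
    tol = 1e-12 * np.maximum(1.0, np.abs(np.mean(x, axis=0)))
    zero = np.flatnonzero(sd <= tol)
    if zero.size:
        raise ValueError(f"zero-variance channel(s): {zero.tolist()}")
    return (x - np.mean(x, axis=0)) / sd


def fit_apply_pca(
    sessions: list[SessionData],
) -> tuple[PCAProjection, list[SessionData]]:
    """Full-rank PCA fit on session-concatenated data, applied to each session.

    Rows of the returned projection are eigenvectors of the concatenated
    covariance, ordered by decreasing eigenvalue, with each row's
    largest-magnitude entry made positive so the basis is reproducible.
    No component is discarded.
    """
    cat = np.concatenate([s.timeseries for s in sessions], axis=0)
    nc = cat.shape[1]
    if cat.shape[0] <= nc:
        raise ValueError("need more concatenated samples than channels for PCA")
    cov = np.cov(cat.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * evals[0]:
        raise ValueError("data are rank-deficient; full-rank PCA is undefined")
    w = evecs.T
    flip = np.sign(w[np.arange(nc), np.argmax(np.abs(w), axis=1)])
    w = w * flip[:, None]
    proj = PCAProjection(w=w, explained_variance=evals)
    return proj, [s.with_timeseries(proj.apply(s.timeseries)) for s in sessions]


def preprocess_sessions(
    sessions: list[SessionData], config: PreprocessConfig
) -> tuple[list[SessionData], PCAProjection | None]:
    """Run the fixed-order pipeline over all sessions."""
    out = []
    for s in sessions:
        ts = s.timeseries
        if config.band is not None:
            ts = bandpass(ts, config.band[0], config.band[1], s.sampling_rate)
        if config.envelope:
            ts = amplitude_envelope(ts)
        if config.smoothing_window > 1:
            ts = moving_average(ts, config.smoothing_window)
        if config.standardise:
            ts = standardise(ts)
        out.append(s.with_timeseries(ts))
    proj = None
    if config.pca:
        proj, out = fit_apply_pca(out)
    return out, proj
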