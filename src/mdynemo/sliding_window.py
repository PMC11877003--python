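"""Model-free baseline: sliding-window features clustered into states.

Per window the per-channel standard deviation ("power") and the
between-channel correlation ("FC") are computed; K-means is run on the
two feature sets *separately*, giving one power state sequence and one FC
state sequence. With a fixed window the baseline cannot follow dynamics
faster than the window length — the deficiency the model-based approach
addresses — which the test suite demonstrates on fast-switching
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "WindowFeatures",
    "window_features",
    "kmeans_states",
    "states_at_samples",
    "state_maps",
    "state_tc_correlation",
    "match_states",
]


@dataclass
class WindowFeatures:
    """Per-window summary statistics on a common window grid."""

    centers: np.ndarray  # centre sample index of each window
    stds: np.ndarray  # (n_windows, Nc)
    correlations: np.ndarray  # (n_windows, Nc*(Nc-1)/2), upper triangle

    @property
    def n_windows(self) -> int:
        return self.centers.shape[0]


def window_features(x: np.ndarray, window: int = 500, step: int = 10) -> WindowFeatures:
    """Windowed standard deviations and vectorised upper-triangle correlations.

    ``x`` is time-major ``(T, Nc)``. Windows start at 0, step, 2·step, …;
    the number of windows is ``floor((T - window) / step) + 1`` and each
    feature row is assigned to its window's centre sample.
    """
    x = np.asarray(x, dtype=float)
    t, nc = x.shape
    if t < window:
        raise ValueError(f"need at least window={window} samples, got {t}")
    starts = np.arange(0, t - window + 1, step)
    iu = np.triu_indices(nc, k=1)
    stds = np.empty((starts.size, nc))
    corrs = np.empty((starts.size, iu[0].size))
    for i, s in enumerate(starts):
        seg = x[s : s + window]
        stds[i] = seg.std(axis=0)
        corrs[i] = np.corrcoef(seg.T)[iu]
    return WindowFeatures(centers=starts + window // 2, stds=stds, correlations=corrs)


def kmeans_states(
    features: np.ndarray, n_states: int, seed=None, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means state assignment of window features (best inertia of restarts)."""
    features = np.asarray(features, dtype=float)
    if n_states > features.shape[0]:
        raise ValueError(
            f"cannot fit {n_states} states to {features.shape[0]} windows"
        )
    km = KMeans(
        n_clusters=n_states,
        n_init=n_restarts,
        random_state=None if seed is None else int(seed) % 2**31,
    ).fit(features)
    return km.labels_.astype(int), km.cluster_centers_


def states_at_samples(centers: np.ndarray, labels: np.ndarray, n_samples: int) -> np.ndarray:
    """Expand window-level labels to per-sample states (nearest window centre)."""
    idx = np.clip(np.searchsorted(centers, np.arange(n_samples)), 0, centers.size - 1)
    left = np.clip(idx - 1, 0, centers.size - 1)
    use_left = np.abs(centers[left] - np.arange(n_samples)) <= np.abs(
        centers[idx] - np.arange(n_samples)
    )
    return labels[np.where(use_left, left, idx)]


def state_maps(
    x: np.ndarray, states: np.ndarray, n_states: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state power and FC maps relative to the across-state average.

    Returns ``(rel_std, rel_corr)``: each state's sample standard
    deviation vector and correlation matrix, minus the unweighted mean
    over states, so the maps sum to zero across states.
    """
    stds, corrs = [], []
    for k in range(n_states):
        sel = x[states == k]
        if sel.shape[0] < 2:
            raise ValueError(f"state {k} has fewer than 2 samples")
        stds.append(sel.std(axis=0))
        corrs.append(np.corrcoef(sel.T))
    stds = np.stack(stds)
    corrs = np.stack(corrs)
    return stds - stds.mean(axis=0), corrs - corrs.mean(axis=0)


def state_tc_correlation(states_a: np.ndarray, states_b: np.ndarray) -> np.ndarray:
    """Pearson correlations between one-hot indicators of two state sequences."""
    if states_a.shape[0] != states_b.shape[0]:
        raise ValueError("state sequences must share the window grid")
    ka, kb = states_a.max() + 1, states_b.max() + 1
    one_a = np.eye(ka)[states_a]
    one_b = np.eye(kb)[states_b]
    if np.any(one_a.std(axis=0) == 0) or np.any(one_b.std(axis=0) == 0):
        raise ValueError("constant state indicator; correlation undefined")
    return np.corrcoef(one_a.T, one_b.T)[:ka, ka:]


def match_states(truth: np.ndarray, estimate: np.ndarray) -> tuple[np.ndarray, float]:
    """Hungarian label matching; returns the relabelled estimate and accuracy."""
    k = int(max(truth.max(), estimate.max())) + 1
    confusion = np.zeros((k, k))
    for a, b in zip(truth, estimate):
        confusion[a, b] += 1
    rows, cols = linear_sum_assignment(-confusion)
    relabel = np.empty(k, dtype=int)
    relabel[cols] = rows
    matched = relabel[estimate]
    return matched, float(np.mean(matched == truth))
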