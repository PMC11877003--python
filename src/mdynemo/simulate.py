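"""Ground-truth simulator: hidden-Markov power and FC dynamics.

Data are drawn from the zero-mean Gaussian observation model with hard
(one-hot) mode mixing: two Markov chains — one selecting the active power
mode, one the active FC mode — drive the covariance
``C_t = E_{s1(t)} R_{s2(t)} E_{s1(t)}``. The chains may be independent
(multi-dynamic ground truth) or literally shared (single-dynamic control).
A task variant forces a designated chain into a designated state in a
window after each stimulus onset, for testing evoked-response inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FCModeSet, PowerModeSet, build_covariance
from .io import SessionData

__all__ = [
    "SimConfig",
    "TaskConfig",
    "GroundTruth",
    "sample_markov_chain",
    "make_random_modes",
    "simulate",
    "simulate_task",
]


@dataclass
class TaskConfig:
    """Stimulus-locked modulation of one Markov chain.

    After each onset the designated chain is forced into ``state`` for
    ``window`` samples, independently per trial with probability
    ``probability``. ``condition`` labels the rows written to the event
    table; a "null" condition (``probability=0``) leaves the resting
    dynamics untouched, for type-I-error testing.
    """

    onsets: list[int] = field(default_factory=list)
    chain: str = "power"  # "power" | "fc" | "both"
    state: int = 0
    window: int = 100
    probability: float = 1.0
    condition: str = "stim"


@dataclass
class SimConfig:
    """Simulation design: desk-scale defaults, long enough for recovery.

    ``task`` may be a single :class:`TaskConfig` or a list of them (one
    per condition); forced windows must not overlap across conditions.
    """

    n_channels: int = 20
    n_power_states: int = 3
    n_fc_states: int = 3
    stay_prob: float = 0.98
    n_samples: int = 12_800
    n_sessions: int = 4
    seed: int = 0
    shared_dynamics: bool = False
    mode_separation: float = 1.0
    fc_separation: float | None = None  # defaults to mode_separation
    sampling_rate: float = 250.0
    task: TaskConfig | list[TaskConfig] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.stay_prob < 1.0):
            raise ValueError("stay_prob must be in (0, 1)")
        for name in ("n_channels", "n_power_states", "n_fc_states", "n_samples", "n_sessions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.shared_dynamics and self.n_power_states != self.n_fc_states:
            raise ValueError("shared dynamics require equal state counts")


@dataclass
class GroundTruth:
    """Generating quantities bundled for recovery scoring."""

    power_states: list[np.ndarray]
    fc_states: list[np.ndarray]
    power_modes: PowerModeSet
    fc_modes: FCModeSet
    sampling_rate: float = 250.0

    def covariances(self, session: int = 0):
        """The exact covariance path of one session (TimeVaryingCovariance)."""
        g = self.power_modes.diagonals[self.power_states[session]]
        f = self.fc_modes.matrices[self.fc_states[session]]
        return build_covariance(g, f)

    @staticmethod
    def one_hot(states: np.ndarray, n_states: int) -> np.ndarray:
        """Indicator time courses, shape ``(T, n_states)``."""
        return np.eye(n_states)[states]


def sample_markov_chain(
    n_states: int, stay_prob: float, n_samples: int, seed=None
) -> np.ndarray:
    """Sample a stationary Markov chain with uniform off-diagonal transitions.

    The initial state is uniform; the transition matrix has ``stay_prob``
    on the diagonal and the remaining mass spread evenly off-diagonal, so
    state lifetimes are geometric with mean ``1 / (1 - stay_prob)``.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = np.random.default_rng(seed)
    if n_states == 1:
        return np.zeros(n_samples, dtype=int)
    states = np.empty(n_samples, dtype=int)
    states[0] = rng.integers(n_states)
    # vectorised: draw stay/switch decisions and switch targets up front
    stay = rng.random(n_samples) < stay_prob
    jump = rng.integers(1, n_states, size=n_samples)
    for t in range(1, n_samples):
        if stay[t]:
            states[t] = states[t - 1]
        else:
            states[t] = (states[t - 1] + jump[t]) % n_states
    return states


def make_random_modes(
    n_channels: int,
    n_power_states: int,
    n_fc_states: int,
    separation: float = 1.0,
    seed=None,
    fc_separation: float | None = None,
) -> tuple[PowerModeSet, FCModeSet]:
    """Draw random generating mode sets with controllable distinctness.

    Power diagonals are log-normal around 1 with log-spread proportional
    to ``separation``; FC matrices are correlation-normalised Wishart-like
    draws whose factors are a shared base plus ``separation``-scaled
    mode-specific low-rank perturbations. ``separation=0`` collapses all
    modes onto a common matrix; larger values make modes more orthogonal.
    """
    if fc_separation is None:
        fc_separation = separation
    if separation < 0 or fc_separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    diags = np.exp(0.5 * separation * rng.standard_normal((n_power_states, n_channels)))
    rank = max(2, n_channels // 2)
    base = rng.standard_normal((n_channels, rank))
    factors = base[None] + fc_separation * rng.standard_normal(
        (n_fc_states, n_channels, rank)
    )
    m = factors @ np.swapaxes(factors, -1, -2) + 1e-6 * np.eye(n_channels)
    d = np.sqrt(np.diagonal(m, axis1=-2, axis2=-1))
    r = m / (d[:, :, None] * d[:, None, :])
    return PowerModeSet(diagonals=diags), FCModeSet(matrices=r)


def _state_cholesky(power: PowerModeSet, fc: FCModeSet) -> np.ndarray:
    """Cholesky factor of C for every (power state, FC state) pair."""
    g = power.diagonals
    c = g[:, None, :, None] * fc.matrices[None] * g[:, None, None, :]
    return np.linalg.cholesky(c)


def simulate(config: SimConfig) -> tuple[list[SessionData], GroundTruth]:
    """Generate sessions of x_t ~ N(0, G_t F_t G_t) under hard HMM mixing."""
    rng = np.random.default_rng(config.seed)
    power_modes, fc_modes = make_random_modes(
        config.n_channels,
        config.n_power_states,
        config.n_fc_states,
        separation=config.mode_separation,
        seed=rng.integers(2**31),
        fc_separation=config.fc_separation,
    )
    chols = _state_cholesky(power_modes, fc_modes)

    sessions, p_states, f_states = [], [], []
    for s in range(config.n_sessions):
        sp = sample_markov_chain(
            config.n_power_states, config.stay_prob, config.n_samples, rng.integers(2**31)
        )
        if config.shared_dynamics:
            sf = sp.copy()
        else:
            sf = sample_markov_chain(
                config.n_fc_states, config.stay_prob, config.n_samples, rng.integers(2**31)
            )
        # dedicated stream so the resting draw is identical with/without a task
        task_rng = np.random.default_rng(rng.integers(2**31))
        sp, sf = _apply_task(sp, sf, config, task_rng)
        z = rng.standard_normal((config.n_samples, config.n_channels))
        x = np.einsum("tij,tj->ti", chols[sp, sf], z)
        sessions.append(
            SessionData(
                id=f"session-{s}",
                x=x.T,
                sampling_rate=config.sampling_rate,
                channel_names=[f"ch{i}" for i in range(config.n_channels)],
            )
        )
        p_states.append(sp)
        f_states.append(sf)
    truth = GroundTruth(
        power_states=p_states,
        fc_states=f_states,
        power_modes=power_modes,
        fc_modes=fc_modes,
        sampling_rate=config.sampling_rate,
    )
    return sessions, truth


def _task_list(config: SimConfig) -> list[TaskConfig]:
    if config.task is None:
        return []
    return list(config.task) if isinstance(config.task, (list, tuple)) else [config.task]


def _apply_task(sp, sf, config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    tasks = [t for t in _task_list(config) if t.onsets]
    if not tasks:
        return sp, sf
    spans = sorted(
        (int(o), int(o) + t.window, t) for t in tasks for o in t.onsets
    )
    for (a, ae, _), (b, _, _) in zip(spans, spans[1:]):
        if b < ae:
            raise ValueError(f"forced windows overlap at onsets {a} and {b}")
    if spans[0][0] < 0 or spans[-1][1] > len(sp):
        raise ValueError("task onsets fall outside the session")
    for onset, _, task in spans:
        if rng.random() < task.probability:
            sl = slice(onset, onset + task.window)
            if task.chain in ("power", "both"):
                sp[sl] = task.state
            if task.chain in ("fc", "both"):
                sf[sl] = task.state
    return sp, sf


def simulate_task(
    config: SimConfig,
) -> tuple[list[SessionData], GroundTruth, pd.DataFrame]:
    """Simulate with stimulus-locked state forcing and return the event table.

    The event table has columns ``onset_sample`` and ``condition`` and is
    identical across sessions (the same trial grid), matching how task
    runs share a stimulus protocol.
    """
    tasks = _task_list(config)
    if not tasks:
        raise ValueError("simulate_task requires config.task")
    sessions, truth = simulate(config)
    events = pd.concat(
        [
            pd.DataFrame(
                {"onset_sample": [int(o) for o in t.onsets], "condition": t.condition}
            )
            for t in tasks
        ],
        ignore_index=True,
    ).sort_values("onset_sample", ignore_index=True)
    return sessions, truth, events
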