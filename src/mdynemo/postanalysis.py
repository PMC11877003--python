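"""Post-fit statistics: renormalisation, mode matching, coupling tests,
network recalculation, task epoching and the two-level evoked-response GLM.

All permutation engines control the family-wise error rate with the
maximum-statistic construction: the null distribution is that of the
maximum (absolute) statistic over every tested element, so a single
threshold applies to the whole family. P-values use the add-one
estimator ``(1 + #{null ≥ observed}) / (1 + n_perm)``. Correlation
inference is done on Fisher-z transformed values throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import FCModeSet, PowerModeSet

__all__ = [
    "EpochSet",
    "StatResult",
    "renormalise",
    "match_modes",
    "relative_power_map",
    "fc_degree_map",
    "maxstat_cosine_test",
    "coupling_matrix",
    "coupling_change",
    "recalc_networks",
    "epoch",
    "evoked_glm",
]


@dataclass
class StatResult:
    """Observed effects, max-statistic null and FWER-corrected p-values."""

    observed: np.ndarray
    null_max: np.ndarray
    pvalues: np.ndarray
    alpha: float = 0.05
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if np.any(self.pvalues < 0) or np.any(self.pvalues > 1):
            raise ValueError("p-values must lie in [0, 1]")
        self.mask = self.pvalues <= self.alpha


@dataclass
class EpochSet:
    """Task-epoched mode time courses for one session.

    ``data`` is trials × time × modes; ``times`` is in seconds relative
    to stimulus onset; ``conditions`` labels each trial.
    """

    data: np.ndarray
    times: np.ndarray
    conditions: list[str]
    session: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if not self.conditions:
            raise ValueError("epoch set has no trials")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")


def _pvalues_from_null(observed_abs: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    return (1.0 + np.sum(null_max >= observed_abs[..., None], axis=-1)) / (
        1.0 + null_max.size
    )


# ---------------------------------------------------------------------------
# maps, matching and renormalisation
# ---------------------------------------------------------------------------


def renormalise(weights: np.ndarray, modes) -> np.ndarray:
    """Reweight mixing coefficients by each mode's overall magnitude.

    A mode with small spatial magnitude can carry a large mixing weight
    yet contribute little to the instantaneous variance/correlation; the
    renormalised time course multiplies each weight by a per-mode scalar
    — the mean power-mode diagonal, or the mean absolute off-diagonal
    correlation — and re-normalises rows to the simplex.
    """
    if isinstance(modes, PowerModeSet):
        w = modes.diagonals.mean(axis=1)
    elif isinstance(modes, FCModeSet):
        r = modes.matrices
        nc = r.shape[-1]
        off = ~np.eye(nc, dtype=bool)
        w = np.abs(r[:, off]).mean(axis=1)
    else:
        w = np.asarray(modes, dtype=float)
    if np.all(w == 0):
        raise ValueError("all mode weights are zero; renormalisation undefined")
    num = weights * w
    return num / num.sum(axis=-1, keepdims=True)


def _cosine_matrix(a: np.ndarray, b: np.ndarray, center: bool = True) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if center:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm map; cosine similarity undefined")
    return (a @ b.T) / np.outer(na, nb)


def match_modes(maps_a: np.ndarray, maps_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match modes of B onto A by mean-centred cosine similarity.

    Returns ``(perm, cos)`` where ``perm[i]`` is the index of the B mode
    assigned to A mode i (Hungarian assignment maximising total matched
    similarity) and ``cos`` is the full cosine matrix. If the counts
    differ, the smaller set is matched into the larger.
    """
    cos = _cosine_matrix(np.atleast_2d(maps_a), np.atleast_2d(maps_b))
    rows, cols = linear_sum_assignment(-cos)
    perm = np.full(cos.shape[0], -1, dtype=int)
    perm[rows] = cols
    return perm, cos


def relative_power_map(modes: PowerModeSet) -> np.ndarray:
    """Per-mode power diagonal minus the across-mode mean (J1 × Nc)."""
    d = modes.diagonals
    return d - d.mean(axis=0)


def fc_degree_map(modes: FCModeSet) -> np.ndarray:
    """Node degree (off-diagonal row sums) per FC mode, across-mode centred."""
    r = modes.matrices.copy()
    idx = np.arange(r.shape[-1])
    r[:, idx, idx] = 0.0
    deg = r.sum(axis=2)
    return deg - deg.mean(axis=0)


def maxstat_cosine_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> StatResult:
    """Are matched cosine similarities larger than chance spatial overlap?

    The null permutes the spatial elements (parcels) of each map in B
    independently, recomputing the full cosine matrix and recording its
    maximum; this preserves each map's value distribution while breaking
    spatial correspondence, and controls the FWER across all pairs.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-values", stacklevel=2)
    if maps_a.shape[1] < 3:
        raise ValueError("need at least 3 spatial elements")
    rng = np.random.default_rng(seed)
    observed = _cosine_matrix(maps_a, maps_b)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm_b = np.stack([rng.permutation(row) for row in maps_b])
        null[p] = _cosine_matrix(maps_a, perm_b).max()
    pvals = _pvalues_from_null(observed, null)
    return StatResult(observed=observed, null_max=null, pvalues=pvals, alpha=alpha)


# ---------------------------------------------------------------------------
# coupling of the two dynamics
# ---------------------------------------------------------------------------


def _session_coupling(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    if np.any(alpha.std(axis=0) == 0) or np.any(beta.std(axis=0) == 0):
        raise ValueError("constant mode time course; correlation undefined")
    j1 = alpha.shape[1]
    return np.corrcoef(alpha.T, beta.T)[:j1, j1:]


def _signflip_test(z: np.ndarray, n_perm: int, rng, alpha: float) -> StatResult:
    """Group max-|mean| sign-flip test over per-session statistic arrays."""
    observed = z.mean(axis=0)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, z.shape[0]))
    null_means = np.tensordot(flips, z, axes=(1, 0)) / z.shape[0]
    null = np.abs(null_means).reshape(n_perm, -1).max(axis=1)
    pvals = _pvalues_from_null(np.abs(observed), null)
    return StatResult(observed=observed, null_max=null, pvalues=pvals, alpha=alpha)


def coupling_matrix(
    alphas: list[np.ndarray],
    betas: list[np.ndarray],
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, StatResult]:
    """Per-session α–β correlation matrices and the group sign-flip test.

    Per-session Pearson correlations are Fisher-z transformed; the group
    null randomly flips the sign of each session's z matrix and takes the
    maximum |mean z| over all (power mode, FC mode) pairs. Returns the
    stacked per-session correlation matrices and a :class:`StatResult`
    whose observed statistic is the mean z.
    """
    if len(alphas) != len(betas):
        raise ValueError("need matching per-session alpha and beta lists")
    if len(alphas) < 2:
        raise ValueError("group inference needs at least 2 sessions")
    r = np.stack([_session_coupling(a, b) for a, b in zip(alphas, betas)])
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    rng = np.random.default_rng(seed)
    return r, _signflip_test(z, n_perm, rng, alpha)


def coupling_change(
    rest_r: np.ndarray,
    task_r: np.ndarray,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> StatResult:
    """Task-minus-rest change in coupling, tested by group sign flips.

    ``rest_r`` and ``task_r`` stack per-session correlation matrices for
    the *same* sessions in the same order, shape (S, J1, J2).
    """
    rest_r = np.asarray(rest_r, dtype=float)
    task_r = np.asarray(task_r, dtype=float)
    if rest_r.shape != task_r.shape:
        raise ValueError("rest and task must cover the same sessions")
    if rest_r.shape[0] < 2:
        raise ValueError("group inference needs at least 2 sessions")
    dz = np.arctanh(np.clip(task_r, -0.999999, 0.999999)) - np.arctanh(
        np.clip(rest_r, -0.999999, 0.999999)
    )
    rng = np.random.default_rng(seed)
    return _signflip_test(dz, n_perm, rng, alpha)


# ---------------------------------------------------------------------------
# network recalculation under a fixed dynamic
# ---------------------------------------------------------------------------


def recalc_networks(
    data,
    mixing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-estimate per-mode covariances given a fixed mixing time course.

    Solves the elementwise linear least squares
    ``min_{C_j} Σ_t ‖x_t x_tᵀ − Σ_j m_jt C_j‖²_F`` — the regression of
    instantaneous second moments onto the mixing design — then
    symmetrises. Returns ``(covariances, power, correlations)``: the raw
    per-mode matrices, their diagonal square roots (power) and implied
    correlation matrices (FC).
    """
    xs = [np.asarray(d, dtype=float) for d in (data if isinstance(data, list) else [data])]
    x = np.concatenate(xs, axis=0)
    m = np.asarray(mixing, dtype=float)
    if m.ndim != 2 or m.shape[0] != x.shape[0]:
        raise ValueError("mixing must be (T, J) aligned with the data")
    j = m.shape[1]
    if np.linalg.matrix_rank(m) < j:
        raise ValueError("mixing design is rank-deficient")
    t, nc = x.shape
    outer = np.einsum("ti,tj->tij", x, x).reshape(t, nc * nc)
    sol, *_ = np.linalg.lstsq(m, outer, rcond=None)
    c = sol.reshape(j, nc, nc)
    c = 0.5 * (c + np.swapaxes(c, -1, -2))
    diag = np.clip(np.diagonal(c, axis1=-2, axis2=-1), 1e-12, None)
    power = np.sqrt(diag)
    corr = c / (power[:, :, None] * power[:, None, :])
    return c, power, corr


# ---------------------------------------------------------------------------
# task epoching and the two-level GLM
# ---------------------------------------------------------------------------


def epoch(
    timecourse: np.ndarray,
    events: pd.DataFrame,
    sampling_rate: float,
    window: tuple[float, float] = (-0.5, 2.0),
    session: int = 0,
) -> EpochSet:
    """Cut a (T, J) time course into stimulus-locked trials.

    The window is in seconds; samples run from ``round(window[0]·fs)`` to
    ``round(window[1]·fs)`` inclusive. Trials whose window leaves the
    recording are dropped (count reported via a warning).
    """
    tc = np.asarray(timecourse, dtype=float)
    lo = int(round(window[0] * sampling_rate))
    hi = int(round(window[1] * sampling_rate))
    times = np.arange(lo, hi + 1) / sampling_rate
    trials, labels, dropped = [], [], 0
    for row in events.itertuples():
        a, b = int(row.onset_sample) + lo, int(row.onset_sample) + hi
        if a < 0 or b >= tc.shape[0]:
            dropped += 1
            continue
        trials.append(tc[a : b + 1])
        labels.append(str(row.condition))
    if dropped:
        warnings.warn(f"dropped {dropped} out-of-bounds trial(s)", stacklevel=2)
    if not trials:
        raise ValueError("no valid trials after windowing")
    return EpochSet(data=np.stack(trials), times=times, conditions=labels, session=session)


def _first_level(
    epochs: EpochSet, conditions: list[str], baseline: tuple[float, float]
) -> np.ndarray:
    """Per-session OLS: condition-mean responses (n_conditions, time, modes).

    Trials are baseline-corrected by subtracting the per-trial mean over
    the pre-stimulus baseline window before regression on the condition
    indicator design (OLS with indicator regressors = condition means).
    """
    sel = (epochs.times >= baseline[0]) & (epochs.times <= baseline[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    data = epochs.data - epochs.data[:, sel, :].mean(axis=1, keepdims=True)
    design = np.stack(
        [np.asarray([c == cond for c in epochs.conditions], dtype=float) for cond in conditions],
        axis=1,
    )
    if np.any(design.sum(axis=0) == 0):
        missing = [c for c, n in zip(conditions, design.sum(axis=0)) if n == 0]
        raise ValueError(f"session {epochs.session} has no trials for {missing}")
    beta, *_ = np.linalg.lstsq(design, data.reshape(data.shape[0], -1), rcond=None)
    return beta.reshape(len(conditions), *data.shape[1:])


def evoked_glm(
    epoch_sets: list[EpochSet],
    contrasts: dict[str, np.ndarray] | None = None,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
    baseline: tuple[float, float] | None = None,
) -> dict[str, StatResult]:
    """Two-level evoked-response GLM with a max-|t| sign-flip null.

    First level: per-session OLS of baseline-corrected epoched time
    courses on condition indicators, contrasted with the given vectors
    (keyed by name; entries follow the sorted condition list; default is
    the mean over conditions). Second level: one-sample group t-test of
    session contrast effects per (time, mode) cell; the null sign-flips
    sessions and takes the maximum |t| over all cells, giving
    FWER-corrected p-values per cell.
    """
    if len(epoch_sets) < 2:
        raise ValueError("group inference needs at least 2 sessions")
    conditions = sorted({c for es in epoch_sets for c in es.conditions})
    if contrasts is None:
        contrasts = {"mean": np.full(len(conditions), 1.0 / len(conditions))}
    for name, vec in contrasts.items():
        if len(np.asarray(vec)) != len(conditions):
            raise ValueError(
                f"contrast {name!r} has {len(np.asarray(vec))} entries for "
                f"conditions {conditions}"
            )
    if baseline is None:
        baseline = (float(epoch_sets[0].times[0]), 0.0)
    effects = np.stack([_first_level(es, conditions, baseline) for es in epoch_sets])
    rng = np.random.default_rng(seed)
    results = {}
    for name, vec in contrasts.items():
        con = np.tensordot(effects, np.asarray(vec, dtype=float), axes=(1, 0))
        results[name] = _max_t_signflip(con, n_perm, rng, alpha)
    return results


def _max_t_signflip(con: np.ndarray, n_perm: int, rng, alpha: float) -> StatResult:
    """One-sample max-|t| sign-flip test over (session, time, mode) effects."""
    s = con.shape[0]

    def tstat(arr):
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(s)
        return mean / np.where(se == 0, np.inf, se)

    observed = tstat(con)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, s))
    null = np.empty(n_perm)
    flat = con.reshape(s, -1)
    for p in range(n_perm):
        null[p] = np.abs(tstat(flips[p][:, None] * flat)).max()
    pvals = _pvalues_from_null(np.abs(observed), null)
    return StatResult(observed=observed, null_max=null, pvalues=pvals, alpha=alpha)
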