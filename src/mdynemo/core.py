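"""Observation model: time-varying covariances built from network modes.

The data model is a zero-mean multivariate Gaussian whose covariance at
time t factorises as ``C_t = G_t F_t G_t``: a diagonal part ``G_t``
(per-channel standard deviations, i.e. "power" of the envelope signal)
and a unit-diagonal correlation part ``F_t`` ("functional connectivity").
Each part is a convex mixture of a small basis of spatial *modes* — fixed
diagonal matrices ``E_j`` for power and correlation matrices ``R_j`` for
FC — with time-varying simplex weights ``alpha`` and ``beta`` obtained by
a softmax of latent logits.

All numerical functions in this module are written against
``autograd.numpy`` so they can be used both on plain arrays and inside
gradient-traced training code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

__all__ = [
    "PowerModeSet",
    "FCModeSet",
    "MixingCoefficients",
    "PCAProjection",
    "TimeVaryingCovariance",
    "softmax_mix",
    "softplus",
    "build_g",
    "build_f",
    "build_covariance",
    "project_modes",
    "log_likelihood",
    "constrain_power",
    "constrain_fc",
    "save_mode_sets",
    "load_mode_sets",
]

#: jitter added before correlation normalisation / PD checks
PD_JITTER = 1e-6


def softplus(x):
    """Numerically stable ``log(1 + exp(x))`` (autograd-compatible)."""
    return anp.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PowerModeSet:
    """Basis of power modes: diagonal matrices with positive diagonals.

    Parameters
    ----------
    diagonals
        Array of shape ``(n_modes, n_channels)`` holding the diagonal of
        each mode matrix ``E_j``. All entries must be strictly positive.
    raw_params
        Optional unconstrained parameters from which the diagonals were
        produced (``diagonals = softplus(raw_params)``).
    """

    diagonals: np.ndarray
    raw_params: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.diagonals = np.asarray(self.diagonals, dtype=float)
        if self.diagonals.ndim != 2:
            raise ValueError("diagonals must be (n_modes, n_channels)")
        if not np.all(np.isfinite(self.diagonals)):
            raise ValueError("power mode diagonals must be finite")
        if np.any(self.diagonals <= 0):
            raise ValueError("power mode diagonals must be strictly positive")

    @property
    def n_modes(self) -> int:
        return self.diagonals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.diagonals.shape[1]

    @property
    def matrices(self) -> np.ndarray:
        """The full diagonal matrices, shape ``(n_modes, Nc, Nc)``."""
        j, nc = self.diagonals.shape
        out = np.zeros((j, nc, nc))
        idx = np.arange(nc)
        out[:, idx, idx] = self.diagonals
        return out


@dataclass
class FCModeSet:
    """Basis of FC modes: unit-diagonal positive-definite (correlation) matrices."""

    matrices: np.ndarray
    raw_params: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_modes, Nc, Nc)")
        r = self.matrices
        if not np.allclose(np.diagonal(r, axis1=-2, axis2=-1), 1.0, atol=1e-8):
            raise ValueError("FC modes must have unit diagonal")
        if not np.allclose(r, np.swapaxes(r, -1, -2), atol=1e-8):
            raise ValueError("FC modes must be symmetric")
        evmin = np.linalg.eigvalsh(r)[:, 0]
        if np.any(evmin <= 0):
            bad = int(np.argmin(evmin))
            raise ValueError(f"FC mode {bad} is not positive-definite (min eig {evmin[bad]:.3e})")

    @property
    def n_modes(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


@dataclass
class MixingCoefficients:
    """Simplex mode time courses and the latent logits that generate them.

    ``alpha`` (power) and ``beta`` (FC) are row-wise softmax transforms of
    the logits ``theta1`` and ``theta2``.
    """

    theta1: np.ndarray
    theta2: np.ndarray
    alpha: np.ndarray = field(init=False)
    beta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        if self.theta1.shape[0] != self.theta2.shape[0]:
            raise ValueError("theta1 and theta2 must cover the same time axis")
        self.alpha = softmax_mix(self.theta1)
        self.beta = softmax_mix(self.theta2)

    @property
    def n_samples(self) -> int:
        return self.theta1.shape[0]


@dataclass
class PCAProjection:
    """Full-rank orthonormal projection; rows are data-covariance eigenvectors."""

    w: np.ndarray
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.ndim != 2 or self.w.shape[1] != n:
            raise ValueError("projection matrix must be square (full-rank PCA)")
        if not np.allclose(self.w @ self.w.T, np.eye(n), atol=1e-8):
            raise ValueError("projection rows are not orthonormal")

    @property
    def n_channels(self) -> int:
        return self.w.shape[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Project time-major data ``(T, Nc)`` onto the eigenbasis."""
        return x @ self.w.T


@dataclass
class TimeVaryingCovariance:
    """A covariance path ``C_t = G_t F_t G_t`` with its two factors.

    ``stddevs`` stores the diagonals of the ``G_t`` (shape ``(T, Nc)``),
    ``correlations`` the ``F_t`` (shape ``(T, Nc, Nc)``) and
    ``covariances`` the products.
    """

    stddevs: np.ndarray
    correlations: np.ndarray
    covariances: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.covariances.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def softmax_mix(logits):
    """Row-wise softmax mapping logits to simplex mixing weights.

    Invariant under adding a constant to a row. Non-finite rows are
    rejected with the offending row index.
    """
    logits = anp.asarray(logits) if not hasattr(logits, "_value") else logits
    vals = np.asarray(getattr(logits, "_value", logits), dtype=float)
    finite_rows = np.isfinite(vals).reshape(-1, vals.shape[-1]).all(axis=1)
    if not finite_rows.all():
        bad = int(np.flatnonzero(~finite_rows)[0])
        raise ValueError(f"non-finite logits at row {bad}")
    shifted = logits - anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=-1, keepdims=True)


def build_g(alpha, power_modes):
    """Mix power modes: diagonal of ``G_t = sum_j alpha_jt E_j``.

    Returns the diagonals, shape ``(T, Nc)`` (the matrices are diagonal).
    """
    diag = power_modes.diagonals if isinstance(power_modes, PowerModeSet) else power_modes
    if alpha.shape[-1] != diag.shape[0]:
        raise ValueError(
            f"alpha has {alpha.shape[-1]} modes but the power mode set has {diag.shape[0]}"
        )
    return alpha @ diag


def build_f(beta, fc_modes):
    """Mix FC modes: ``F_t = sum_j beta_jt R_j``, shape ``(T, Nc, Nc)``.

    A convex combination of unit-diagonal PD matrices is itself a valid
    correlation matrix.
    """
    mats = fc_modes.matrices if isinstance(fc_modes, FCModeSet) else fc_modes
    if beta.shape[-1] != mats.shape[0]:
        raise ValueError(
            f"beta has {beta.shape[-1]} modes but the FC mode set has {mats.shape[0]}"
        )
    return anp.einsum("...tj,jpq->...tpq", beta, mats)


def build_covariance(g, f) -> TimeVaryingCovariance:
    """Combine factors into covariances ``C_t = G_t F_t G_t``."""
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(g <= 0):
        raise ValueError("G diagonals must be strictly positive")
    c = g[..., :, None] * f * g[..., None, :]
    return TimeVaryingCovariance(stddevs=g, correlations=f, covariances=c)


def _mix_covariance(g, f):
    """Traced covariance product (no type wrapping), for training code."""
    return g[..., :, None] * f * g[..., None, :]


def project_modes(projection: PCAProjection, matrices):
    """Similarity-transform mode matrices into the PCA basis: ``W M Wᵀ``.

    Accepts a stacked array ``(J, Nc, Nc)`` (or a single matrix); works for
    power modes (as full diagonal matrices) and FC modes alike. Because W
    is orthonormal, eigenvalues — and therefore positive-definiteness —
    are preserved.
    """
    w = projection.w if isinstance(projection, PCAProjection) else np.asarray(projection)
    n = w.shape[0]
    if not np.allclose(w @ w.T, np.eye(n), atol=1e-8):
        raise ValueError("projection matrix is not orthonormal")
    m = anp.asarray(matrices) if not hasattr(matrices, "_value") else matrices
    return anp.einsum("pi,...ij,qj->...pq", w, m, w)


# --- Gaussian log-likelihood as an autograd primitive ----------------------
#
# The gradient of sum_t log N(x_t | 0, C_t) with respect to C_t is
# 0.5 (C^-1 x x^T C^-1 - C^-1); defining this analytically avoids tracing
# batched Cholesky factorisations and is the hot path of training.


@primitive
def _gaussian_ll(c, x):
    chol = np.linalg.cholesky(c)
    z = np.linalg.solve(chol, x[..., None])[..., 0]
    quad = np.sum(z**2, axis=-1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=-2, axis2=-1)), axis=-1)
    n = x.shape[-1]
    return np.sum(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


def _gaussian_ll_vjp_c(ans, c, x):
    def vjp(g):
        cinv = np.linalg.inv(c)
        a = np.einsum("...ij,...j->...i", cinv, x)
        return g * 0.5 * (a[..., :, None] * a[..., None, :] - cinv)

    return vjp


def _gaussian_ll_vjp_x(ans, c, x):
    def vjp(g):
        cinv = np.linalg.inv(c)
        return g * (-np.einsum("...ij,...j->...i", cinv, x))

    return vjp


defvjp(_gaussian_ll, _gaussian_ll_vjp_c, _gaussian_ll_vjp_x)


def log_likelihood(x: np.ndarray, cov) -> float:
    """Zero-mean Gaussian log-likelihood ``sum_t log N(x_t | 0, C_t)``.

    Parameters
    ----------
    x
        Time-major data, shape ``(T, Nc)`` (leading batch axes allowed).
    cov
        A :class:`TimeVaryingCovariance` or an array of covariances with
        shape broadcastable to ``x``'s time axis.
    """
    c = cov.covariances if isinstance(cov, TimeVaryingCovariance) else cov
    c_arr = np.asarray(getattr(c, "_value", c), dtype=float)
    # diagnose non-PD time points before handing to the primitive
    try:
        np.linalg.cholesky(c_arr)
    except np.linalg.LinAlgError:
        flat = c_arr.reshape(-1, c_arr.shape[-1], c_arr.shape[-1])
        for t, m in enumerate(flat):
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"covariance at time index {t} is not positive-definite"
                ) from None
        raise
    return _gaussian_ll(c, anp.asarray(x) if not hasattr(x, "_value") else x)


# ---------------------------------------------------------------------------
# constraint maps (unconstrained parameters -> valid mode sets)
# ---------------------------------------------------------------------------


def _power_diagonals(raw):
    """softplus link producing strictly positive diagonals (traced)."""
    return softplus(raw) + 1e-8


def _fc_matrices(raw):
    """Unit-diagonal PD matrices from unconstrained square factors (traced).

    The lower triangle of each raw matrix is used as a Cholesky-like
    factor L; ``M = L Lᵀ + jitter·I`` is then normalised to a correlation
    matrix ``D^{-1/2} M D^{-1/2}`` with ``D = diag(M)``. Total and smooth
    in the raw parameters.
    """
    nc = raw.shape[-1]
    tril = np.tril(np.ones((nc, nc)))
    low = raw * tril
    m = anp.einsum("...pq,...rq->...pr", low, low) + PD_JITTER * anp.eye(nc)
    d = anp.sqrt(anp.diagonal(m, axis1=-1, axis2=-2))
    return m / (d[..., :, None] * d[..., None, :])


def _full_covariances(raw):
    """Unconstrained factors -> symmetric PD matrices (single-dynamic modes)."""
    nc = raw.shape[-1]
    tril = np.tril(np.ones((nc, nc)))
    low = raw * tril
    return anp.einsum("...pq,...rq->...pr", low, low) + PD_JITTER * anp.eye(nc)


def constrain_power(raw: np.ndarray) -> PowerModeSet:
    """Map unconstrained ``(J1, Nc)`` values to a valid :class:`PowerModeSet`."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw power parameters must be finite")
    return PowerModeSet(diagonals=_power_diagonals(raw), raw_params=raw)


def constrain_fc(raw: np.ndarray) -> FCModeSet:
    """Map unconstrained ``(J2, Nc, Nc)`` factors to a valid :class:`FCModeSet`."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw FC parameters must be finite")
    return FCModeSet(matrices=_fc_matrices(raw), raw_params=raw)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def save_mode_sets(
    path,
    power: PowerModeSet,
    fc: FCModeSet,
    channel_names: list[str] | None = None,
) -> None:
    """Write mode sets to HDF5 with a JSON metadata sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("power_modes/E", data=power.diagonals)
        f.create_dataset("fc_modes/R", data=fc.matrices)
    meta = {
        "n_power_modes": power.n_modes,
        "n_fc_modes": fc.n_modes,
        "n_channels": power.n_channels,
        "channel_names": channel_names
        or [f"ch{i}" for i in range(power.n_channels)],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_mode_sets(path) -> tuple[PowerModeSet, FCModeSet]:
    """Read mode sets written by :func:`save_mode_sets`."""
    import h5py

    with h5py.File(path, "r") as f:
        diags = f["power_modes/E"][()]
        mats = f["fc_modes/R"][()]
    return PowerModeSet(diagonals=diags), FCModeSet(matrices=mats)
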