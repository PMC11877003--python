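"""Variational training of the multi-dynamic (and single-dynamic) model.

The generative model places a recurrent prior over two latent logit
sequences — one driving power mixing, one FC mixing. An LSTM consumes the
concatenated logit history of *both* dynamics and emits, through
per-dynamic linear heads, the mean and (softplus-linked) scale of the
next logits, so the two dynamics remain mutually informed while staying
free to decouple. The posterior is amortised: a bidirectional LSTM over
the data sequence produces per-time-point mean-field Gaussian factors for
each dynamic. Training minimises the variational free energy

    loss(sequence) = −E_q[log p(x_t | θ)]  (one reparameterised sample)
                   + Σ_{t≥2} Σ_k KL( q(θ_t^k) ‖ p(θ_t^k | θ_{1:t−1}) )

with Adam over mini-batches of fixed-length sequences; the first time
step carries no KL penalty (the prior is conditional-only), and recurrent
state is reset at every sequence boundary.

The single-dynamic special case uses one logit sequence whose simplex
weights mix full covariance matrices directly (no power/FC split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import _networks as nets
from .core import (
    PD_JITTER,
    FCModeSet,
    MixingCoefficients,
    PCAProjection,
    PowerModeSet,
    _full_covariances,
    _gaussian_ll,
    _fc_matrices,
    _mix_covariance,
    _power_diagonals,
    softmax_mix,
    softplus,
)
from .io import SessionData

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "chunk_sessions",
    "reparameterised_sample",
    "free_energy",
    "train",
    "train_single_dynamic",
    "infer_mixing",
    "dual_estimate",
]

_SCALE_FLOOR = 1e-6


@dataclass
class TrainingConfig:
    """Knobs of the optimisation; defaults are desk-scale.

    ``n_power_modes``/``n_fc_modes`` default to 4 each (the two counts are
    independent); ``sequence_length`` of 200 samples keeps the LSTMs on
    stable gradient horizons. ``kl_anneal_epochs`` linearly ramps the KL
    weight from 0 to 1; ``n_random_starts`` restarts keep the best final
    loss. For the single-dynamic model only ``n_power_modes`` is used.
    """

    n_power_modes: int = 4
    n_fc_modes: int = 4
    sequence_length: int = 200
    batch_size: int = 32
    n_epochs: int = 40
    learning_rate: float = 1e-3
    kl_anneal_epochs: int = 10
    n_random_starts: int = 10
    seed: int = 0
    hidden_size: int = 64
    do_pca: bool = False

    def __post_init__(self) -> None:
        if self.sequence_length < 2:
            raise ValueError("sequence_length must be >= 2")
        for name in (
            "n_power_modes",
            "n_fc_modes",
            "batch_size",
            "n_epochs",
            "n_random_starts",
            "hidden_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    """A fitted model: parameters, configuration and training diagnostics."""

    params: dict
    config: TrainingConfig
    n_channels: int
    single_dynamic: bool = False
    pca: PCAProjection | None = None
    loss_history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    restart_losses: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def power_modes(self) -> PowerModeSet:
        if self.single_dynamic:
            raise AttributeError("single-dynamic models expose mode_covariances")
        return PowerModeSet(
            diagonals=_power_diagonals(self.params["power_raw"]),
            raw_params=self.params["power_raw"],
        )

    @property
    def fc_modes(self) -> FCModeSet:
        if self.single_dynamic:
            raise AttributeError("single-dynamic models expose mode_covariances")
        return FCModeSet(
            matrices=_fc_matrices(self.params["fc_raw"]),
            raw_params=self.params["fc_raw"],
        )

    @property
    def mode_covariances(self) -> np.ndarray:
        """Full covariance modes of the single-dynamic model, (J, Nc, Nc)."""
        if not self.single_dynamic:
            raise AttributeError("multi-dynamic models expose power_modes/fc_modes")
        return _full_covariances(self.params["cov_raw"])


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------


def _session_arrays(data) -> list[np.ndarray]:
    out = []
    for d in data:
        ts = d.timeseries if isinstance(d, SessionData) else np.asarray(d, dtype=float)
        out.append(ts)
    return out


def chunk_sessions(data, sequence_length: int) -> np.ndarray:
    """Cut sessions into non-overlapping fixed-length sequences.

    Sequences never span a session boundary; the trailing remainder of
    each session is dropped. Sessions shorter than ``sequence_length``
    are excluded with a warning.
    """
    chunks = []
    for i, ts in enumerate(_session_arrays(data)):
        n = ts.shape[0] // sequence_length
        if n == 0:
            warnings.warn(
                f"session {i} has {ts.shape[0]} samples < sequence length "
                f"{sequence_length}; excluded",
                stacklevel=2,
            )
            continue
        chunks.append(
            ts[: n * sequence_length].reshape(n, sequence_length, ts.shape[1])
        )
    if not chunks:
        raise ValueError("no session is at least one sequence long")
    return np.concatenate(chunks, axis=0)


def reparameterised_sample(m, s, noise):
    """Location-scale reparameterisation ``θ = m + s · ε`` (gradients flow)."""
    return m + s * noise


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def _posterior_stats(params, x, single_dynamic: bool):
    """Posterior means and scales per dynamic from the BiLSTM encoder."""
    h = nets.bilstm(params["post_fwd"], params["post_bwd"], x)
    if single_dynamic:
        m = nets.dense(params["inf_m1"], h)
        s = softplus(nets.dense(params["inf_s1"], h)) + _SCALE_FLOOR
        return m, s
    m1 = nets.dense(params["inf_m1"], h)
    m2 = nets.dense(params["inf_m2"], h)
    s1 = softplus(nets.dense(params["inf_s1"], h)) + _SCALE_FLOOR
    s2 = softplus(nets.dense(params["inf_s2"], h)) + _SCALE_FLOOR
    return anp.concatenate([m1, m2], axis=2), anp.concatenate([s1, s2], axis=2)


def _prior_stats(params, theta_hist, single_dynamic: bool):
    """Prior mean/scale at t=2..T from the LSTM over θ_{1:t−1} (both dynamics)."""
    hp = nets.lstm(params["prior"], theta_hist)
    if single_dynamic:
        mu = nets.dense(params["gen_m1"], hp)
        sig = softplus(nets.dense(params["gen_s1"], hp)) + _SCALE_FLOOR
        return mu, sig
    mu = anp.concatenate(
        [nets.dense(params["gen_m1"], hp), nets.dense(params["gen_m2"], hp)], axis=2
    )
    sig = anp.concatenate(
        [
            softplus(nets.dense(params["gen_s1"], hp)) + _SCALE_FLOOR,
            softplus(nets.dense(params["gen_s2"], hp)) + _SCALE_FLOOR,
        ],
        axis=2,
    )
    return mu, sig


def _observation_cov(params, theta, n_power_modes: int, single_dynamic: bool, pca_w):
    """Time-varying covariance implied by logits θ (traced)."""
    if single_dynamic:
        alpha = softmax_mix(theta)
        cov_modes = _full_covariances(params["cov_raw"])
        c = anp.einsum("btj,jpq->btpq", alpha, cov_modes)
    else:
        alpha = softmax_mix(theta[:, :, :n_power_modes])
        beta = softmax_mix(theta[:, :, n_power_modes:])
        e = _power_diagonals(params["power_raw"])
        r = _fc_matrices(params["fc_raw"])
        g = alpha @ e
        f = anp.einsum("btj,jpq->btpq", beta, r)
        c = _mix_covariance(g, f)
    if pca_w is not None:
        c = anp.einsum("pi,btij,qj->btpq", pca_w, c, pca_w)
    return c


def gaussian_kl(m, s, mu, sig):
    """Closed-form KL( N(m, s²) ‖ N(mu, sig²) ), elementwise."""
    return anp.log(sig / s) + (s**2 + (m - mu) ** 2) / (2.0 * sig**2) - 0.5


def free_energy(
    params: dict,
    x: np.ndarray,
    noise: np.ndarray,
    n_power_modes: int,
    single_dynamic: bool = False,
    pca_w: np.ndarray | None = None,
    kl_scale: float = 1.0,
) -> float:
    """Variational free energy of a batch, averaged over sequences.

    ``x`` is ``(B, T, Nc)``; ``noise`` is the standard-normal draw used by
    the reparameterised posterior sample, ``(B, T, J_total)``. Passing the
    noise explicitly makes the loss a deterministic function, which the
    test suite exploits to check it term by term against an independent
    straight-line computation.
    """
    b = x.shape[0]
    m, s = _posterior_stats(params, x, single_dynamic)
    theta = reparameterised_sample(m, s, noise)
    c = _observation_cov(params, theta, n_power_modes, single_dynamic, pca_w)
    ll = _gaussian_ll(c, x)
    mu, sig = _prior_stats(params, theta[:, :-1, :], single_dynamic)
    kl = gaussian_kl(m[:, 1:], s[:, 1:], mu, sig)
    loss = (-ll + kl_scale * anp.sum(kl)) / b
    return loss


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _data_stats(sequences: np.ndarray):
    flat = sequences.reshape(-1, sequences.shape[-1])
    sub = flat[:: max(1, flat.shape[0] // 20000)]
    return np.cov(sub.T)


def _cluster_warm_start(sequences: np.ndarray, j1: int, j2: int, rng):
    """Initial per-mode stds/correlations from K-means on windowed features.

    Mixture-model training is prone to mode collapse when all modes start
    near the static solution; clustering short-window standard deviations
    and correlations (coarse, but directionally right) breaks the symmetry
    along real covariance regimes. Returns ``None`` when the data cannot
    support it (too short, degenerate), in which case the caller falls
    back to noisy static initialisation.
    """
    from .sliding_window import kmeans_states, window_features

    flat = sequences.reshape(-1, sequences.shape[-1])
    window, step = 100, 25
    if flat.shape[0] < window * max(j1, j2):
        return None
    feats = window_features(flat, window=window, step=step)
    if not (
        np.isfinite(feats.stds).all() and np.isfinite(feats.correlations).all()
    ):
        return None
    nc = flat.shape[1]
    iu = np.triu_indices(nc, 1)
    lab_p, _ = kmeans_states(feats.stds, j1, seed=int(rng.integers(2**31)), n_restarts=5)
    lab_f, _ = kmeans_states(
        feats.correlations, j2, seed=int(rng.integers(2**31)), n_restarts=5
    )
    power_raw = np.empty((j1, nc))
    fc_raw = np.empty((j2, nc, nc))
    for j in range(j1):
        stds = feats.stds[lab_p == j].mean(axis=0)
        power_raw[j] = np.log(np.expm1(np.clip(stds, 1e-2, None)))
    for j in range(j2):
        cm = np.eye(nc)
        cm[iu] = feats.correlations[lab_f == j].mean(axis=0)
        cm = cm + cm.T - np.eye(nc)
        # project onto the PD cone, then renormalise to a correlation matrix
        w, v = np.linalg.eigh(cm)
        cm = (v * np.clip(w, 1e-3, None)) @ v.T
        d = np.sqrt(np.diag(cm))
        cm = cm / np.outer(d, d)
        fc_raw[j] = np.linalg.cholesky(cm + PD_JITTER * np.eye(nc))
    return power_raw, fc_raw


def _init_params(
    config: TrainingConfig,
    n_channels: int,
    cov: np.ndarray,
    rng,
    single_dynamic: bool,
    sequences: np.ndarray | None = None,
) -> dict:
    h, nc = config.hidden_size, n_channels
    j1, j2 = config.n_power_modes, config.n_fc_modes
    params = {
        "post_fwd": nets.init_lstm(nc, h, rng),
        "post_bwd": nets.init_lstm(nc, h, rng),
    }
    if single_dynamic:
        j_total = j1
        params["prior"] = nets.init_lstm(j_total, h, rng)
        for name, n_out in (("inf_m1", j1), ("inf_s1", j1)):
            params[name] = nets.init_dense(2 * h, n_out, rng)
        for name, n_out in (("gen_m1", j1), ("gen_s1", j1)):
            params[name] = nets.init_dense(h, n_out, rng)
        warm = (
            _cluster_warm_start(sequences, j1, j1, rng) if sequences is not None else None
        )
        if warm is not None:
            praw, fraw = warm
            stds = softplus(praw) + 1e-8
            corr = np.einsum("jpq,jrq->jpr", fraw, fraw)
            covs = stds[:, :, None] * corr * stds[:, None, :]
            params["cov_raw"] = np.linalg.cholesky(
                covs + PD_JITTER * np.eye(nc)
            ) + 0.05 * rng.standard_normal((j1, nc, nc))
        else:
            chol = np.linalg.cholesky(cov + 1e-6 * np.eye(nc))
            params["cov_raw"] = chol[None] + 0.05 * rng.standard_normal((j1, nc, nc))
    else:
        j_total = j1 + j2
        params["prior"] = nets.init_lstm(j_total, h, rng)
        for name, n_out in (("inf_m1", j1), ("inf_m2", j2), ("inf_s1", j1), ("inf_s2", j2)):
            params[name] = nets.init_dense(2 * h, n_out, rng)
        for name, n_out in (("gen_m1", j1), ("gen_m2", j2), ("gen_s1", j1), ("gen_s2", j2)):
            params[name] = nets.init_dense(h, n_out, rng)
        warm = (
            _cluster_warm_start(sequences, j1, j2, rng) if sequences is not None else None
        )
        if warm is not None:
            praw, fraw = warm
            params["power_raw"] = praw + 0.1 * rng.standard_normal((j1, nc))
            params["fc_raw"] = fraw + 0.05 * rng.standard_normal((j2, nc, nc))
        else:
            # fall back to the static solution (unit-ish stds, sample
            # correlation) with enough spread to break mode symmetry
            std = np.sqrt(np.clip(np.diag(cov), 1e-3, None))
            corr = cov / np.outer(std, std)
            params["power_raw"] = np.log(np.expm1(std))[None] + 0.5 * rng.standard_normal(
                (j1, nc)
            )
            chol = np.linalg.cholesky(corr + 1e-6 * np.eye(nc))
            params["fc_raw"] = chol[None] + 0.2 * rng.standard_normal((j2, nc, nc))
    return params


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _train_one_start(sequences, config, pca_w, single_dynamic, seed):
    rng = np.random.default_rng(seed)
    cov = _data_stats(sequences)
    params = _init_params(
        config, sequences.shape[-1], cov, rng, single_dynamic, sequences=sequences
    )
    opt = nets.Adam(params, lr=config.learning_rate)
    n_seq = sequences.shape[0]
    j_total = config.n_power_modes + (0 if single_dynamic else config.n_fc_modes)
    loss_and_grad = value_and_grad(free_energy)
    history = []
    first_epoch_loss = None
    for epoch in range(config.n_epochs):
        kl_scale = min(1.0, (epoch + 1) / max(1, config.kl_anneal_epochs))
        order = rng.permutation(n_seq)
        epoch_losses = []
        for lo in range(0, n_seq, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = sequences[idx]
            noise = rng.standard_normal((batch.shape[0], batch.shape[1], j_total))
            loss, grads = loss_and_grad(
                params,
                batch,
                noise,
                config.n_power_modes,
                single_dynamic,
                pca_w,
                kl_scale,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch}, batch starting at {lo}"
                )
            params = opt.step(params, grads)
            epoch_losses.append(float(loss))
        history.append(float(np.mean(epoch_losses)))
        if first_epoch_loss is None:
            first_epoch_loss = history[0]
        elif history[-1] > 10.0 * abs(first_epoch_loss) + 1e3:
            raise FloatingPointError(f"divergence at epoch {epoch}")
    return params, np.asarray(history)


def _train(data, config: TrainingConfig, pca, single_dynamic: bool) -> TrainedModel:
    sequences = chunk_sessions(data, config.sequence_length)
    if float(np.std(sequences)) < 1e-8:
        warnings.warn("degenerate (near-constant) data; fit is not meaningful", stacklevel=2)
    pca_w = None
    if pca is not None:
        pca_w = pca.w if isinstance(pca, PCAProjection) else np.asarray(pca)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_random_starts)
    best = None
    finals = []
    for start, child in enumerate(seeds):
        try:
            params, history = _train_one_start(
                sequences, config, pca_w, single_dynamic, child
            )
        except FloatingPointError as err:
            warnings.warn(f"restart {start} aborted: {err}", stacklevel=2)
            finals.append(np.inf)
            continue
        finals.append(history[-1])
        if best is None or history[-1] < best[1][-1]:
            best = (params, history)
    if best is None:
        raise RuntimeError("all training restarts diverged")
    params, history = best
    return TrainedModel(
        params=params,
        config=config,
        n_channels=sequences.shape[-1],
        single_dynamic=single_dynamic,
        pca=pca if isinstance(pca, PCAProjection) else None,
        loss_history=history,
        restart_losses=np.asarray(finals),
    )


def train(data, config: TrainingConfig, pca: PCAProjection | None = None) -> TrainedModel:
    """Fit the multi-dynamic model; returns the best of ``n_random_starts``.

    ``data`` is a list of :class:`~mdynemo.io.SessionData` (or time-major
    arrays), already preprocessed (standardised, and PCA-projected when a
    projection is supplied — the projection is folded into the likelihood
    so the learned modes live in the original channel space).
    """
    return _train(data, config, pca, single_dynamic=False)


def train_single_dynamic(
    data, config: TrainingConfig, pca: PCAProjection | None = None
) -> TrainedModel:
    """Fit the single-dynamic special case (one logit sequence, full-covariance modes)."""
    return _train(data, config, pca, single_dynamic=True)


# ---------------------------------------------------------------------------
# posterior inference on (possibly unseen) sessions
# ---------------------------------------------------------------------------


def _session_posterior_means(model: TrainedModel, ts: np.ndarray) -> np.ndarray:
    """Posterior mean logits for one session, covering every sample.

    Sessions are processed in non-overlapping windows of the training
    sequence length; a final overlapping window covers the remainder so
    the output length equals the input length.
    """
    t_seq = model.config.sequence_length
    t = ts.shape[0]
    if t < t_seq:
        raise ValueError(f"session shorter ({t}) than the sequence length ({t_seq})")
    starts = list(range(0, t - t_seq + 1, t_seq))
    if starts[-1] + t_seq < t:
        starts.append(t - t_seq)
    batch = np.stack([ts[s : s + t_seq] for s in starts])
    m, _ = _posterior_stats(model.params, batch, model.single_dynamic)
    m = np.asarray(m)
    out = np.empty((t, m.shape[-1]))
    for i, s in enumerate(starts):
        out[s : s + t_seq] = m[i]  # later (overlapping) windows win
    return out


def infer_mixing(model: TrainedModel, data) -> list[MixingCoefficients]:
    """Amortised posterior mixing coefficients for each session.

    Softmax of the posterior mean logits; output length equals session
    length. For single-dynamic models ``theta2``/``beta`` duplicate the
    single dynamic so downstream code has a uniform interface.
    """
    out = []
    for ts in _session_arrays(data):
        if ts.shape[1] != model.n_channels:
            raise ValueError(
                f"session has {ts.shape[1]} channels; model expects {model.n_channels}"
            )
        m = _session_posterior_means(model, ts)
        if model.single_dynamic:
            out.append(MixingCoefficients(theta1=m, theta2=m))
        else:
            j1 = model.config.n_power_modes
            out.append(MixingCoefficients(theta1=m[:, :j1], theta2=m[:, j1:]))
    return out


def dual_estimate(
    model: TrainedModel,
    session,
    n_iter: int = 400,
    learning_rate: float = 0.02,
) -> tuple[PowerModeSet, FCModeSet]:
    """Session-level mode sets with the group temporal model frozen.

    The session's mixing-coefficient posterior (from the group model's
    amortised encoder) is held fixed and only the observation parameters
    are re-optimised on the session's data, by gradient descent on the
    negative log-likelihood. The KL term does not involve the observation
    parameters, so this is the free-energy optimum for fixed q.
    """
    if model.single_dynamic:
        raise ValueError("dual estimation is defined for the multi-dynamic model")
    (ts,) = _session_arrays([session])
    j1 = model.config.n_power_modes
    if ts.shape[0] < 2 * model.n_channels:
        warnings.warn("session is short relative to channel count; estimates may be noisy", stacklevel=2)
    m = _session_posterior_means(model, ts)
    alpha = softmax_mix(m[:, :j1])[None]
    beta = softmax_mix(m[:, j1:])[None]
    x = ts[None]
    pca_w = model.pca.w if model.pca is not None else None

    obs = {
        "power_raw": model.params["power_raw"].copy(),
        "fc_raw": model.params["fc_raw"].copy(),
    }

    def nll(obs_params):
        e = _power_diagonals(obs_params["power_raw"])
        r = _fc_matrices(obs_params["fc_raw"])
        g = alpha @ e
        f = anp.einsum("btj,jpq->btpq", beta, r)
        c = _mix_covariance(g, f)
        if pca_w is not None:
            c = anp.einsum("pi,btij,qj->btpq", pca_w, c, pca_w)
        return -_gaussian_ll(c, x) / x.shape[1]

    vag = value_and_grad(nll)
    opt = nets.Adam(obs, lr=learning_rate)
    for _ in range(n_iter):
        _, grads = vag(obs)
        obs = opt.step(obs, grads)
    return (
        PowerModeSet(diagonals=_power_diagonals(obs["power_raw"]), raw_params=obs["power_raw"]),
        FCModeSet(matrices=_fc_matrices(obs["fc_raw"]), raw_params=obs["fc_raw"]),
    )
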