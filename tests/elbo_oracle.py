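"""Independent straight-line computation of the variational free energy.

Deliberately re-implements the whole forward computation — LSTM cells,
posterior/prior heads, mode constraints, Gaussian density and KL — with
plain loops and scipy, sharing no code with the package's traced path.
Used by the test suite as the term-by-term oracle for the training loss.
"""

import numpy as np
from scipy.stats import multivariate_normal


def _sig(v):
    return 1.0 / (1.0 + np.exp(-v))


def lstm_loop(p, x):
    """Single-sequence LSTM forward pass, one explicit step at a time."""
    h_dim = p["b"].shape[0] // 4
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    outs = []
    for t in range(x.shape[0]):
        z = x[t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sig(z[:h_dim])
        f = _sig(z[h_dim : 2 * h_dim] + 1.0)
        g = np.tanh(z[2 * h_dim : 3 * h_dim])
        o = _sig(z[3 * h_dim :])
        c = f * c + i * g
        h = o * np.tanh(c)
        outs.append(h.copy())
    return np.asarray(outs)


def _softplus(v):
    return np.log1p(np.exp(v))


def _head(p, h):
    return h @ p["W"] + p["b"]


def _softmax_rows(theta):
    out = np.empty_like(theta)
    for t in range(theta.shape[0]):
        e = np.exp(theta[t] - theta[t].max())
        out[t] = e / e.sum()
    return out


def _corr_from_raw(raw):
    n = raw.shape[-1]
    out = np.empty_like(raw)
    for j in range(raw.shape[0]):
        low = np.tril(raw[j])
        m = low @ low.T + 1e-6 * np.eye(n)
        d = np.sqrt(np.diag(m))
        out[j] = m / np.outer(d, d)
    return out


def oracle_free_energy(params, x, noise, j1, j2, single_dynamic=False, pca_w=None):
    """Eq-by-eq free energy: −log-likelihood plus KL summed from t = 2."""
    b, t_seq, n = x.shape
    floor = 1e-6
    total = 0.0
    for bi in range(b):
        hf = lstm_loop(params["post_fwd"], x[bi])
        hb = lstm_loop(params["post_bwd"], x[bi][::-1])[::-1]
        h = np.concatenate([hf, hb], axis=1)
        if single_dynamic:
            m = _head(params["inf_m1"], h)
            s = _softplus(_head(params["inf_s1"], h)) + floor
        else:
            m = np.concatenate(
                [_head(params["inf_m1"], h), _head(params["inf_m2"], h)], axis=1
            )
            s = np.concatenate(
                [
                    _softplus(_head(params["inf_s1"], h)) + floor,
                    _softplus(_head(params["inf_s2"], h)) + floor,
                ],
                axis=1,
            )
        theta = m + s * noise[bi]

        # observation model
        if single_dynamic:
            alpha = _softmax_rows(theta)
            modes = np.empty((j1, n, n))
            for j in range(j1):
                low = np.tril(params["cov_raw"][j])
                modes[j] = low @ low.T + 1e-6 * np.eye(n)
            covs = np.einsum("tj,jpq->tpq", alpha, modes)
        else:
            alpha = _softmax_rows(theta[:, :j1])
            beta = _softmax_rows(theta[:, j1:])
            e = _softplus(params["power_raw"]) + 1e-8
            r = _corr_from_raw(params["fc_raw"])
            covs = np.empty((t_seq, n, n))
            for t in range(t_seq):
                g = np.diag(alpha[t] @ e)
                f = sum(beta[t, j] * r[j] for j in range(j2))
                covs[t] = g @ f @ g
        if pca_w is not None:
            covs = np.einsum("pi,tij,qj->tpq", pca_w, covs, pca_w)
        ll = sum(
            multivariate_normal.logpdf(x[bi, t], mean=np.zeros(n), cov=covs[t])
            for t in range(t_seq)
        )

        # recurrent prior over θ history of both dynamics
        hp = lstm_loop(params["prior"], theta[:-1])
        if single_dynamic:
            mu = _head(params["gen_m1"], hp)
            sig = _softplus(_head(params["gen_s1"], hp)) + floor
        else:
            mu = np.concatenate(
                [_head(params["gen_m1"], hp), _head(params["gen_m2"], hp)], axis=1
            )
            sig = np.concatenate(
                [
                    _softplus(_head(params["gen_s1"], hp)) + floor,
                    _softplus(_head(params["gen_s2"], hp)) + floor,
                ],
                axis=1,
            )
        kl = 0.0
        for t in range(1, t_seq):
            for d in range(m.shape[1]):
                kl += 0.5 * (
                    np.log(sig[t - 1, d] ** 2 / s[t, d] ** 2)
                    + (s[t, d] ** 2 + (m[t, d] - mu[t - 1, d]) ** 2) / sig[t - 1, d] ** 2
                    - 1.0
                )
        total += -ll + kl
    return total / b
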