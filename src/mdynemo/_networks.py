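"""Minimal LSTM / dense building blocks on autograd-traced numpy.

Conventions (kept deliberately plain so an independent re-implementation
is straightforward):

* LSTM gate order in the stacked weight matrices is (input, forget, cell,
  output); the forget gate carries a +1 bias offset at evaluation time.
* ``lstm`` consumes batch-major sequences ``(B, T, n_in)`` and returns the
  hidden-state sequence ``(B, T, n_hidden)``; initial state is zero and
  state is never carried across sequences.
* ``bilstm`` concatenates a forward pass and a time-reversed backward
  pass, giving ``(B, T, 2·n_hidden)``.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.misc.flatten import flatten


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def init_lstm(n_in: int, n_hidden: int, rng) -> dict:
    s = 1.0 / np.sqrt(n_in + n_hidden)
    return {
        "Wx": rng.uniform(-s, s, (n_in, 4 * n_hidden)),
        "Wh": rng.uniform(-s, s, (n_hidden, 4 * n_hidden)),
        "b": np.zeros(4 * n_hidden),
    }


def init_dense(n_in: int, n_out: int, rng, scale: float = 0.1) -> dict:
    return {"W": rng.normal(0.0, scale, (n_in, n_out)), "b": np.zeros(n_out)}


def dense(p: dict, x):
    return x @ p["W"] + p["b"]


def lstm(p: dict, x):
    """Run an LSTM over ``x`` of shape (B, T, n_in); returns (B, T, H)."""
    b, t, _ = x.shape
    h_dim = p["b"].shape[0] // 4
    # project all inputs up front; the loop then only touches the recurrence
    xp = anp.reshape(anp.reshape(x, (b * t, -1)) @ p["Wx"], (b, t, 4 * h_dim)) + p["b"]
    h = anp.zeros((b, h_dim))
    c = anp.zeros((b, h_dim))
    outs = []
    for ti in range(t):
        z = xp[:, ti, :] + h @ p["Wh"]
        i = sigmoid(z[:, :h_dim])
        f = sigmoid(z[:, h_dim : 2 * h_dim] + 1.0)
        g = anp.tanh(z[:, 2 * h_dim : 3 * h_dim])
        o = sigmoid(z[:, 3 * h_dim :])
        c = f * c + i * g
        h = o * anp.tanh(c)
        outs.append(h)
    return anp.stack(outs, axis=1)


def bilstm(p_fwd: dict, p_bwd: dict, x):
    """Bidirectional LSTM: concatenated forward and reversed-backward passes."""
    fwd = lstm(p_fwd, x)
    bwd = lstm(p_bwd, x[:, ::-1, :])[:, ::-1, :]
    return anp.concatenate([fwd, bwd], axis=2)


class Adam:
    """Adam on an arbitrary nested parameter structure (via flattening)."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        flat, self.unflatten = flatten(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0

    def step(self, params, grads):
        flat, _ = flatten(params)
        gflat, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * gflat
        self.v = self.b2 * self.v + (1 - self.b2) * gflat**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return self.unflatten(flat - self.lr * mhat / (np.sqrt(vhat) + self.eps))
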