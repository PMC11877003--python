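"""Shared fixtures: desk-scale training runs reused across acceptance checks.

The training-based fixtures run the full variational fit on simulated
data. To keep the default test run within a CI-scale time budget they use
a reduced data size (2 sessions × 6,400 samples instead of the
simulator's default 4 × 12,800) and a single random start; the scientific
thresholds they are checked against are unchanged.
"""

import sys
from pathlib import Path

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

sys.path.insert(0, str(Path(__file__).parent))

from mdynemo.inference import TrainingConfig, train, train_single_dynamic, infer_mixing
from mdynemo.preprocess import standardise
from mdynemo.simulate import GroundTruth, SimConfig, simulate

ACCEPT_TRAIN = dict(
    n_power_modes=3,
    n_fc_modes=3,
    sequence_length=200,
    batch_size=16,
    n_epochs=40,
    learning_rate=7.5e-3,
    kl_anneal_epochs=10,
    n_random_starts=1,
    seed=11,
    hidden_size=32,
)


def mean_matched_r(tc_true, tc_est):
    """Hungarian-matched mean Pearson r between two sets of time courses."""
    j1 = tc_true.shape[1]
    r = np.corrcoef(tc_true.T, tc_est.T)[:j1, j1:]
    rows, cols = linear_sum_assignment(-r)
    return float(r[rows, cols].mean()), cols, r


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _prep(sessions):
    return [s.with_timeseries(standardise(s.timeseries)) for s in sessions]


def _truth_indicators(truth, j1, j2):
    oh_p = np.concatenate([GroundTruth.one_hot(s, j1) for s in truth.power_states])
    oh_f = np.concatenate([GroundTruth.one_hot(s, j2) for s in truth.fc_states])
    return oh_p, oh_f


@pytest.fixture(scope="session")
def multi_dynamic_fit():
    """Multi-dynamic model trained on an independent-chains simulation (Nc=20, 3+3 states)."""
    cfg = SimConfig(n_channels=20, n_samples=6400, n_sessions=2, seed=101)
    sessions, truth = simulate(cfg)
    scales = np.mean([s.timeseries.std(axis=0) for s in sessions], axis=0)
    data = _prep(sessions)
    model = train(data, TrainingConfig(**ACCEPT_TRAIN))
    mixing = infer_mixing(model, data)
    alpha = np.concatenate([m.alpha for m in mixing])
    beta = np.concatenate([m.beta for m in mixing])
    oh_p, oh_f = _truth_indicators(truth, 3, 3)
    return {
        "model": model,
        "truth": truth,
        "scales": scales,
        "alpha": alpha,
        "beta": beta,
        "oh_power": oh_p,
        "oh_fc": oh_f,
        "mixing": mixing,
    }


@pytest.fixture(scope="session")
def shared_dynamic_fit():
    """Multi-dynamic model trained on a shared-chain (single-dynamic) simulation."""
    cfg = SimConfig(
        n_channels=20, n_samples=6400, n_sessions=2, seed=102, shared_dynamics=True
    )
    sessions, truth = simulate(cfg)
    data = _prep(sessions)
    model = train(data, TrainingConfig(**ACCEPT_TRAIN))
    mixing = infer_mixing(model, data)
    return {
        "model": model,
        "truth": truth,
        "alpha": np.concatenate([m.alpha for m in mixing]),
        "beta": np.concatenate([m.beta for m in mixing]),
    }


@pytest.fixture(scope="session")
def single_dynamic_fit():
    """Single-dynamic model trained on multi-dynamic data whose power signal dominates."""
    cfg = SimConfig(
        n_channels=20,
        n_samples=6400,
        n_sessions=2,
        seed=103,
        mode_separation=1.2,
        fc_separation=0.6,
    )
    sessions, truth = simulate(cfg)
    data = _prep(sessions)
    model = train_single_dynamic(data, TrainingConfig(**ACCEPT_TRAIN))
    mixing = infer_mixing(model, data)
    oh_p, oh_f = _truth_indicators(truth, 3, 3)
    return {
        "model": model,
        "truth": truth,
        "alpha": np.concatenate([m.alpha for m in mixing]),
        "oh_power": oh_p,
        "oh_fc": oh_f,
    }
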