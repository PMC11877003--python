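"""Post-fit statistics: renormalisation, matching, coupling, GLM, recalculation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mdynemo.core import FCModeSet, PowerModeSet, build_covariance, constrain_fc
from mdynemo.postanalysis import (
    EpochSet,
    coupling_change,
    coupling_matrix,
    epoch,
    evoked_glm,
    fc_degree_map,
    match_modes,
    maxstat_cosine_test,
    recalc_networks,
    relative_power_map,
    renormalise,
)

RNG = np.random.default_rng(7)


def simplex(t, j, rng=RNG):
    w = rng.random((t, j))
    return w / w.sum(axis=1, keepdims=True)


class TestRenormalise:
    def test_equal_weights_identity(self):
        alpha = simplex(20, 3)
        power = PowerModeSet(diagonals=np.full((3, 4), 1.7))
        assert np.allclose(renormalise(alpha, power), alpha)

    def test_single_mode_constant_one(self):
        alpha = np.ones((10, 1))
        power = PowerModeSet(diagonals=np.full((1, 4), 0.3))
        assert np.allclose(renormalise(alpha, power), 1.0)

    def test_matches_stated_formula(self):
        alpha = simplex(15, 3)
        fc = constrain_fc(RNG.standard_normal((3, 5, 5)))
        out = renormalise(alpha, fc)
        off = ~np.eye(5, dtype=bool)
        w = np.array([np.abs(r[off]).mean() for r in fc.matrices])
        expected = alpha * w
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            renormalise(simplex(5, 2), np.zeros(2))


class TestMatchModes:
    def test_recovers_shuffle(self):
        a = RNG.standard_normal((4, 10))
        shuffle = np.array([2, 0, 3, 1])
        perm, cos = match_modes(a, a[shuffle])
        assert np.array_equal(shuffle[perm], np.arange(4))
        assert np.allclose(cos[np.arange(4), perm], 1.0)

    def test_orthogonal_maps_near_zero(self):
        a = np.eye(3) - 1 / 3  # mean-centred orthogonal rows
        perm, cos = match_modes(a, RNG.standard_normal((3, 3)) * 0 + np.roll(a, 1, 0))
        assert np.allclose(np.sort(cos[0]), np.sort(cos[1]))

    def test_assignment_matches_exhaustive_search(self):
        a = RNG.standard_normal((4, 8))
        b = RNG.standard_normal((4, 8))
        perm, cos = match_modes(a, b)
        best = max(
            itertools.permutations(range(4)),
            key=lambda p: sum(cos[i, p[i]] for i in range(4)),
        )
        assert np.array_equal(perm, np.asarray(best))

    def test_zero_norm_rejected(self):
        a = np.ones((2, 4))  # mean-centred to zero
        with pytest.raises(ValueError, match="zero-norm"):
            match_modes(a, a)


class TestMaps:
    def test_identical_modes_give_zero_maps(self):
        power = PowerModeSet(diagonals=np.tile([1.0, 2.0, 3.0], (4, 1)))
        assert np.allclose(relative_power_map(power), 0.0)
        fc = FCModeSet(matrices=np.broadcast_to(np.eye(3), (4, 3, 3)).copy())
        assert np.allclose(fc_degree_map(fc), 0.0)

    def test_maps_center_to_zero_across_modes(self):
        power = PowerModeSet(diagonals=np.abs(RNG.standard_normal((4, 6))) + 0.1)
        assert np.allclose(relative_power_map(power).sum(axis=0), 0.0, atol=1e-12)
        fc = constrain_fc(RNG.standard_normal((4, 6, 6)))
        assert np.allclose(fc_degree_map(fc).sum(axis=0), 0.0, atol=1e-12)

    def test_degree_matches_naive_double_loop(self):
        fc = constrain_fc(RNG.standard_normal((3, 5, 5)))
        deg = np.zeros((3, 5))
        for j in range(3):
            for n in range(5):
                deg[j, n] = sum(
                    fc.matrices[j, n, m] for m in range(5) if m != n
                )
        expected = deg - deg.mean(axis=0)
        assert np.allclose(fc_degree_map(fc), expected, atol=1e-12)


class TestMaxstatCosine:
    def test_self_match_highly_significant(self):
        maps = RNG.standard_normal((4, 38))
        res = maxstat_cosine_test(maps, maps, n_perm=1000, seed=0)
        assert np.all(res.pvalues[np.arange(4), np.arange(4)] <= 0.01)
        assert np.all(res.mask[np.arange(4), np.arange(4)])

    def test_zero_permutations_rejected(self):
        maps = RNG.standard_normal((2, 5))
        with pytest.raises(ValueError):
            maxstat_cosine_test(maps, maps, n_perm=0)

    def test_few_permutations_warn(self):
        maps = RNG.standard_normal((2, 6))
        with pytest.warns(UserWarning, match="coarse"):
            maxstat_cosine_test(maps, maps, n_perm=50, seed=0)


class TestCoupling:
    @staticmethod
    def sessions_with_shared_dynamics(n_sessions=8, t=2000, j=3):
        rng = np.random.default_rng(11)
        alphas, betas = [], []
        for _ in range(n_sessions):
            a = simplex(t, j, rng)
            alphas.append(a)
            betas.append(a + 0.01 * rng.standard_normal((t, j)))
        return alphas, betas

    def test_shared_dynamics_diagonal_significant(self):
        alphas, betas = self.sessions_with_shared_dynamics()
        r, res = coupling_matrix(alphas, betas, n_perm=500, seed=1)
        assert r.shape == (8, 3, 3)
        assert np.all(res.mask[np.arange(3), np.arange(3)])

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            coupling_matrix([simplex(100, 2)], [simplex(100, 2)])

    def test_constant_time_course_rejected(self):
        a = np.ones((100, 1))
        with pytest.raises(ValueError, match="constant"):
            coupling_matrix([a, a], [simplex(100, 2), simplex(100, 2)])

    def test_change_task_equals_rest_not_significant(self):
        rng = np.random.default_rng(3)
        r = np.clip(0.1 * rng.standard_normal((8, 3, 3)), -0.9, 0.9)
        res = coupling_change(r, r, n_perm=500, seed=2)
        assert not res.mask.any()  # zero difference everywhere

    def test_change_detects_induced_coupling(self):
        rng = np.random.default_rng(4)
        rest = np.clip(0.05 * rng.standard_normal((10, 3, 3)), -0.9, 0.9)
        task = rest.copy()
        task[:, 1, 2] += 0.5
        res = coupling_change(rest, task, n_perm=500, seed=5)
        assert res.mask[1, 2]
        assert res.pvalues[1, 2] <= 0.05

    def test_session_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same sessions"):
            coupling_change(np.zeros((4, 2, 2)), np.zeros((5, 2, 2)))


class TestRecalcNetworks:
    def test_one_hot_mixing_recovers_segment_covariance(self):
        rng = np.random.default_rng(6)
        c0 = np.array([[2.0, 0.5], [0.5, 1.0]])
        c1 = np.array([[1.0, -0.4], [-0.4, 3.0]])
        x0 = rng.multivariate_normal([0, 0], c0, 20_000)
        x1 = rng.multivariate_normal([0, 0], c1, 20_000)
        x = np.vstack([x0, x1])
        m = np.zeros((40_000, 2))
        m[:20_000, 0] = 1
        m[20_000:, 1] = 1
        cov, power, corr = recalc_networks(x, m)
        assert np.allclose(cov[0], x0.T @ x0 / 20_000, atol=1e-8)
        assert np.allclose(cov[1], x1.T @ x1 / 20_000, atol=1e-8)
        assert np.allclose(power[0], np.sqrt(np.diag(cov[0])))

    def test_single_constant_mode_gives_global_second_moment(self):
        x = RNG.standard_normal((5000, 3))
        cov, _, _ = recalc_networks(x, np.ones((5000, 1)))
        assert np.allclose(cov[0], x.T @ x / 5000, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        m = np.ones((100, 2))  # two identical columns
        with pytest.raises(ValueError, match="rank"):
            recalc_networks(RNG.standard_normal((100, 2)), m)


class TestEpoch:
    def test_onset_at_zero_dropped(self):
        events = pd.DataFrame({"onset_sample": [0, 400], "condition": ["a", "a"]})
        with pytest.warns(UserWarning, match="dropped 1"):
            es = epoch(RNG.standard_normal((1000, 2)), events, 250.0)
        assert es.data.shape[0] == 1

    def test_window_arithmetic(self):
        events = pd.DataFrame({"onset_sample": [500], "condition": ["a"]})
        es = epoch(RNG.standard_normal((1001, 2)), events, 250.0)
        assert es.data.shape == (1, 626, 2)  # −125…+500 samples inclusive
        assert np.isclose(es.times[0], -0.5) and np.isclose(es.times[-1], 2.0)

    def test_epoch_count_bookkeeping(self):
        onsets = [200, 400, 600, 950]
        events = pd.DataFrame({"onset_sample": onsets, "condition": "a"})
        with pytest.warns(UserWarning):
            es = epoch(RNG.standard_normal((1200, 1)), events, 250.0)
        assert es.data.shape[0] == 3  # 950 + 500 > 1199 is dropped

    def test_no_valid_trials_rejected(self):
        events = pd.DataFrame({"onset_sample": [5], "condition": ["a"]})
        with pytest.raises(ValueError, match="no valid trials"), pytest.warns(UserWarning):
            epoch(RNG.standard_normal((300, 1)), events, 250.0)


def make_epochs(n_sessions=6, n_trials=20, n_times=50, n_modes=3, effect=0.0, seed=0):
    """Epoch sets with optional post-onset effect on mode 0 for condition 'a'."""
    rng = np.random.default_rng(seed)
    times = np.linspace(-0.5, 1.5, n_times)
    sets = []
    for s in range(n_sessions):
        data = rng.standard_normal((n_trials, n_times, n_modes))
        conds = ["a" if i % 2 == 0 else "b" for i in range(n_trials)]
        post = times > 0.2
        for i, c in enumerate(conds):
            if c == "a":
                data[i][np.ix_(post, [0])] += effect
        sets.append(EpochSet(data=data, times=times, conditions=conds, session=s))
    return sets


class TestEvokedGLM:
    def test_detects_induced_response_in_correct_cell(self):
        sets = make_epochs(n_sessions=12, effect=1.5, seed=1)
        res = evoked_glm(
            sets,
            contrasts={"a-b": np.array([1.0, -1.0])},
            n_perm=300,
            seed=2,
        )["a-b"]
        post = sets[0].times > 0.25
        assert res.mask[np.ix_(post, [0])].mean() > 0.8
        assert not res.mask[:, 1:].any()

    def test_all_zero_epochs_no_significance_no_crash(self):
        sets = make_epochs(effect=0.0, seed=3)
        for es in sets:
            es.data[:] = 0.0
        res = evoked_glm(sets, n_perm=100, seed=0)["mean"]
        assert not res.mask.any()

    def test_absent_condition_in_contrast_rejected(self):
        sets = make_epochs()
        with pytest.raises(ValueError, match="contrast"):
            evoked_glm(sets, contrasts={"bad": np.array([1.0, -1.0, 0.0])})

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            evoked_glm(make_epochs(n_sessions=1))

    def test_pvalues_within_unit_interval(self):
        res = evoked_glm(make_epochs(seed=9), n_perm=100, seed=4)["mean"]
        assert np.all((res.pvalues > 0) & (res.pvalues <= 1))
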