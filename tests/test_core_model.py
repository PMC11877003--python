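"""Core observation model: mode mixing, covariance construction, likelihood."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mdynemo.core import (
    FCModeSet,
    PCAProjection,
    PowerModeSet,
    build_covariance,
    build_f,
    build_g,
    constrain_fc,
    constrain_power,
    load_mode_sets,
    log_likelihood,
    project_modes,
    save_mode_sets,
    softmax_mix,
)

RNG = np.random.default_rng(1234)


def random_mode_sets(nc=4, j1=3, j2=3, rng=RNG):
    power = constrain_power(rng.standard_normal((j1, nc)))
    fc = constrain_fc(rng.standard_normal((j2, nc, nc)))
    return power, fc


def random_simplex(t, j, rng=RNG):
    w = rng.random((t, j))
    return w / w.sum(axis=1, keepdims=True)


class TestSoftmaxMix:
    def test_symmetry(self):
        out = softmax_mix(np.zeros((1, 4)))
        assert np.allclose(out, 0.25)

    def test_shift_invariance(self):
        row = np.array([[0.3, 1.2, -0.5]])
        assert np.allclose(softmax_mix(row), softmax_mix(row + 7.0))

    def test_matches_defining_formula(self):
        row = np.array([1.0, 2.0, 3.0])
        expected = np.exp(row) / np.exp(row).sum()
        assert np.allclose(softmax_mix(row[None]), expected[None])

    def test_rows_are_simplex(self):
        out = softmax_mix(RNG.standard_normal((50, 5)) * 10)
        assert np.all(out >= 0)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_nonfinite_rejected_with_row(self):
        bad = np.zeros((3, 2))
        bad[1, 0] = np.inf
        with pytest.raises(ValueError, match="row 1"):
            softmax_mix(bad)


class TestBuildG:
    def test_single_identity_mode(self):
        power = PowerModeSet(diagonals=np.ones((1, 3)))
        g = build_g(np.ones((5, 1)), power)
        assert np.allclose(g, 1.0)

    def test_simplex_vertex_and_midpoint(self):
        power = PowerModeSet(diagonals=np.array([[2.0, 2.0], [5.0, 5.0]]))
        assert np.allclose(build_g(np.array([[1.0, 0.0]]), power), 2.0)
        assert np.allclose(build_g(np.array([[0.5, 0.5]]), power), 3.5)

    def test_dimension_mismatch(self):
        power = PowerModeSet(diagonals=np.ones((2, 3)))
        with pytest.raises(ValueError, match="modes"):
            build_g(np.ones((4, 3)) / 3, power)


class TestBuildF:
    def test_single_identity_mode(self):
        fc = FCModeSet(matrices=np.eye(2)[None])
        assert np.allclose(build_f(np.ones((4, 1)), fc), np.eye(2))

    def test_convex_midpoint_two_channels(self):
        r1 = np.array([[1.0, 0.8], [0.8, 1.0]])
        r2 = np.eye(2)
        fc = FCModeSet(matrices=np.stack([r1, r2]))
        f = build_f(np.array([[0.5, 0.5]]), fc)
        assert np.allclose(f[0], [[1.0, 0.4], [0.4, 1.0]])

    def test_random_mixture_is_correlation(self):
        _, fc = random_mode_sets(nc=5, j2=3)
        f = build_f(random_simplex(20, 3), fc)
        assert np.allclose(np.diagonal(f, axis1=-2, axis2=-1), 1.0)
        assert np.linalg.eigvalsh(f).min() > 0


class TestBuildCovariance:
    def test_identity(self):
        cov = build_covariance(np.ones((3, 2)), np.broadcast_to(np.eye(2), (3, 2, 2)))
        assert np.allclose(cov.covariances, np.eye(2))

    def test_direct_product(self):
        g = np.array([[2.0, 3.0]])
        f = np.array([[[1.0, 0.5], [0.5, 1.0]]])
        cov = build_covariance(g, f)
        assert np.allclose(cov.covariances[0], [[4.0, 3.0], [3.0, 9.0]])

    def test_matches_naive_triple_product(self):
        power, fc = random_mode_sets(nc=4)
        g = build_g(random_simplex(10, 3), power)
        f = build_f(random_simplex(10, 3), fc)
        cov = build_covariance(g, f)
        for t in range(10):
            gm = np.diag(g[t])
            assert np.allclose(cov.covariances[t], gm @ f[t] @ gm, atol=1e-12)

    def test_nonpositive_g_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_covariance(np.zeros((1, 2)), np.broadcast_to(np.eye(2), (1, 2, 2)))

    def test_decomposition_round_trip(self):
        power, fc = random_mode_sets(nc=5)
        cov = build_covariance(
            build_g(random_simplex(8, 3), power), build_f(random_simplex(8, 3), fc)
        )
        std = np.sqrt(np.diagonal(cov.covariances, axis1=-2, axis2=-1))
        corr = cov.covariances / (std[:, :, None] * std[:, None, :])
        rebuilt = std[:, :, None] * corr * std[:, None, :]
        assert np.allclose(rebuilt, cov.covariances, atol=1e-8)
        assert np.allclose(corr, cov.correlations, atol=1e-8)

    def test_convexity_closure_random_draws(self):
        """PD is closed under mixing: many random constructions stay valid."""
        power, fc = random_mode_sets(nc=6, j1=4, j2=4)
        cov = build_covariance(
            build_g(random_simplex(200, 4), power), build_f(random_simplex(200, 4), fc)
        )
        np.linalg.cholesky(cov.covariances)  # raises if any fails


class TestProjection:
    @staticmethod
    def random_orthonormal(n, rng=RNG):
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        return q

    def test_identity_projection(self):
        _, fc = random_mode_sets(nc=4)
        proj = PCAProjection(w=np.eye(4))
        assert np.allclose(project_modes(proj, fc.matrices), fc.matrices)

    def test_isotropic_invariance(self):
        w = self.random_orthonormal(5)
        assert np.allclose(project_modes(PCAProjection(w=w), np.eye(5)), np.eye(5), atol=1e-12)

    def test_eigenvalues_preserved(self):
        power, fc = random_mode_sets(nc=5)
        cov = build_covariance(
            build_g(random_simplex(6, 3), power), build_f(random_simplex(6, 3), fc)
        )
        w = self.random_orthonormal(5)
        proj = project_modes(PCAProjection(w=w), cov.covariances)
        assert np.allclose(
            np.linalg.eigvalsh(proj), np.linalg.eigvalsh(cov.covariances), atol=1e-8
        )

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            project_modes(np.ones((3, 3)), np.eye(3))

    def test_log_likelihood_projection_equivalence(self):
        """|det W| = 1, so the likelihood is invariant under the rotation."""
        power, fc = random_mode_sets(nc=4)
        g = build_g(random_simplex(30, 3), power)
        f = build_f(random_simplex(30, 3), fc)
        cov = build_covariance(g, f)
        x = RNG.standard_normal((30, 4))
        w = self.random_orthonormal(4)
        ll_raw = log_likelihood(x, cov)
        ll_proj = log_likelihood(x @ w.T, project_modes(PCAProjection(w=w), cov.covariances))
        assert np.isclose(ll_raw, ll_proj, atol=1e-6)


class TestLogLikelihood:
    def test_standard_normal_at_mode(self):
        ll = log_likelihood(np.zeros((1, 1)), np.ones((1, 1, 1)))
        assert np.isclose(ll, -0.5 * np.log(2 * np.pi))

    def test_zero_data_gives_half_logdet(self):
        power, fc = random_mode_sets(nc=3)
        cov = build_covariance(
            build_g(random_simplex(4, 3), power), build_f(random_simplex(4, 3), fc)
        )
        ll = log_likelihood(np.zeros((4, 3)), cov)
        expected = -0.5 * np.sum(
            [np.log(np.linalg.det(2 * np.pi * c)) for c in cov.covariances]
        )
        assert np.isclose(ll, expected, atol=1e-8)

    def test_matches_scipy_density(self):
        power, fc = random_mode_sets(nc=3)
        cov = build_covariance(
            build_g(random_simplex(5, 3), power), build_f(random_simplex(5, 3), fc)
        )
        x = RNG.standard_normal((5, 3))
        expected = sum(
            multivariate_normal.logpdf(x[t], mean=np.zeros(3), cov=cov.covariances[t])
            for t in range(5)
        )
        assert np.isclose(log_likelihood(x, cov), expected, atol=1e-8)

    def test_non_pd_reported_with_time_index(self):
        c = np.broadcast_to(np.eye(2), (4, 2, 2)).copy()
        c[2] = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError, match="time index 2"):
            log_likelihood(np.zeros((4, 2)), c)


class TestConstraints:
    def test_zero_raw_power_gives_log_two(self):
        power = constrain_power(np.zeros((2, 3)))
        assert np.allclose(power.diagonals, np.log(2.0), atol=1e-6)

    def test_identity_factor_gives_identity_correlation(self):
        fc = constrain_fc(np.broadcast_to(np.eye(3), (2, 3, 3)).copy())
        assert np.allclose(fc.matrices, np.eye(3), atol=1e-5)

    def test_random_raw_satisfies_invariants(self):
        fc = constrain_fc(RNG.standard_normal((4, 6, 6)))
        assert np.allclose(np.diagonal(fc.matrices, axis1=-2, axis2=-1), 1.0, atol=1e-8)
        assert np.linalg.eigvalsh(fc.matrices).min() > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            constrain_power(np.array([[np.nan, 0.0]]))


class TestTypesAndSerialisation:
    def test_power_mode_invariants_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            PowerModeSet(diagonals=np.array([[1.0, -0.1]]))

    def test_fc_mode_invariants_enforced(self):
        bad = np.array([[[1.0, 2.0], [2.0, 1.0]]])  # unit diag but indefinite
        with pytest.raises(ValueError, match="positive-definite"):
            FCModeSet(matrices=bad)

    def test_pca_projection_requires_orthonormal_rows(self):
        with pytest.raises(ValueError, match="orthonormal"):
            PCAProjection(w=np.ones((2, 2)))

    def test_hdf5_round_trip(self, tmp_path):
        power, fc = random_mode_sets(nc=4)
        path = tmp_path / "modes.h5"
        save_mode_sets(path, power, fc, channel_names=["a", "b", "c", "d"])
        power2, fc2 = load_mode_sets(path)
        assert np.array_equal(power.diagonals, power2.diagonals)
        assert np.array_equal(fc.matrices, fc2.matrices)
        assert path.with_suffix(".h5.json").exists()
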