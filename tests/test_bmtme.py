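"""Matrix-normal primitives and Gibbs-sampler correctness.

The Gaussian full-conditional updates are certified against an
independent dense oracle: the same conditional built explicitly as a
vec/Kronecker multivariate normal, whose exact mean and covariance the
empirical moments of repeated Gibbs draws must match to Monte-Carlo
precision.  The inverse-Wishart updates are checked against the
closed-form conditional mean.
"""

import numpy as np
import pytest
from scipy import stats

from mtmepred import SimulationConfig, simulate_dataset
from mtmepred.bmtme import (
    BMTMEPriors,
    BMTMERegressor,
    BMTMEState,
    _workspace,
    gibbs_step_b1,
    gibbs_step_b2,
    gibbs_step_beta,
    gibbs_step_Re,
    gibbs_step_sigma_E,
    gibbs_step_sigma_t,
    matrix_normal_logpdf,
    predict,
    run_gibbs,
    sample_matrix_normal,
)


def _vec(M):
    return np.asarray(M).flatten(order="F")


class TestMatrixNormalLogpdf:
    def test_scalar_standard_normal_at_mean(self):
        lp = matrix_normal_logpdf(np.array([[0.0]]), np.array([[0.0]]),
                                  np.array([[1.0]]), np.array([[1.0]]))
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_explicit_kronecker_density(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, p = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            M = rng.standard_normal((n, p))
            H = rng.standard_normal((n, p))
            A = rng.standard_normal((n, n + 1))
            Omega = A @ A.T + n * np.eye(n)
            B = rng.standard_normal((p, p + 1))
            Sigma = B @ B.T + p * np.eye(p)
            lp = matrix_normal_logpdf(M, H, Omega, Sigma)
            ref = stats.multivariate_normal.logpdf(
                _vec(M), _vec(H), np.kron(Sigma, Omega))
            assert lp == pytest.approx(ref, abs=1e-10)

    def test_kronecker_scale_invariance(self):
        rng = np.random.default_rng(1)
        M, H = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        Omega = np.eye(3) + 0.1
        Sigma = np.eye(2) * 2.0
        c = 3.7
        assert matrix_normal_logpdf(M, H, c * Omega, Sigma / c) == pytest.approx(
            matrix_normal_logpdf(M, H, Omega, Sigma), abs=1e-10)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            matrix_normal_logpdf(np.zeros((2, 2)), np.zeros((2, 2)),
                                 -np.eye(2), np.eye(2))


class TestSampleMatrixNormal:
    def test_moments_identity(self):
        rng = np.random.default_rng(2)
        draws = np.array([
            sample_matrix_normal(np.zeros((2, 2)), np.eye(2), np.eye(2), rng)
            for _ in range(10_000)
        ])
        flat = draws.reshape(10_000, 4)
        assert np.abs(flat.mean(axis=0)).max() < 4 / np.sqrt(10_000)
        np.testing.assert_allclose(np.cov(flat.T), np.eye(4), atol=0.06)

    def test_column_correlation(self):
        rng = np.random.default_rng(3)
        Sigma = np.array([[1.0, 0.9], [0.9, 1.0]])
        draws = np.array([
            sample_matrix_normal(np.zeros((1, 2)), np.eye(1), Sigma, rng)[0]
            for _ in range(10_000)
        ])
        r = np.corrcoef(draws.T)[0, 1]
        assert r == pytest.approx(0.9, abs=0.02)

    def test_degenerate_limit_returns_mean(self):
        rng = np.random.default_rng(4)
        H = np.arange(6, dtype=float).reshape(3, 2)
        eps = 1e-18
        draw = sample_matrix_normal(H, eps * np.eye(3), eps * np.eye(2), rng)
        np.testing.assert_allclose(draw, H, atol=1e-8)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="dimension"):
            sample_matrix_normal(np.zeros((2, 2)), np.eye(3), np.eye(2), rng)


@pytest.fixture(scope="module")
def conditional_instance():
    """A 4-line, 2-env, 2-trait instance with an arbitrary valid state."""
    ds, _ = simulate_dataset(SimulationConfig(J=4, I=2, L=2, p=30, seed=5))
    work = _workspace(ds, include_gxe=True)
    rng = np.random.default_rng(0)
    state = BMTMEState(
        beta=rng.standard_normal((2, 2)),
        b1=rng.standard_normal((4, 2)),
        b2=rng.standard_normal((8, 2)),
        Sigma_t=np.array([[1.0, 0.3], [0.3, 0.8]]),
        Sigma_E=np.array([[1.2, 0.4], [0.4, 0.9]]),
        Re=np.array([[0.6, 0.1], [0.1, 0.5]]),
    )
    priors = BMTMEPriors(beta_precision=0.7).resolved(2, 2)
    return ds, work, state, priors


def _empirical_moments(step, state, work, priors, attr, n=20_000, seed=1):
    rng = np.random.default_rng(seed)
    draws = np.array([
        _vec(getattr(step(state, work, priors, rng, Y=work.ds.Y), attr))
        for _ in range(n)
    ])
    return draws.mean(axis=0), np.cov(draws.T), n


class TestGaussianConditionals:
    """Each Gaussian block vs the dense vec/Kronecker conditional."""

    def test_beta_block(self, conditional_instance):
        ds, work, st, pri = conditional_instance
        Re_inv = np.linalg.inv(st.Re)
        Yr = ds.Y - st.b1[work.line_of_row] - st.b2[work.env_of_row * 4 + work.line_of_row]
        Q = np.kron(Re_inv, work.X.T @ work.X) + pri.beta_precision * np.eye(4)
        mean = np.linalg.solve(Q, _vec(work.X.T @ Yr @ Re_inv))
        cov = np.linalg.inv(Q)
        emp_mean, emp_cov, n = _empirical_moments(
            gibbs_step_beta, st, work, pri, "beta")
        tol = 5 * np.sqrt(np.diag(cov).max() / n)
        assert np.abs(emp_mean - mean).max() < tol
        assert np.abs(emp_cov - cov).max() < 12 * np.diag(cov).max() / np.sqrt(n)

    def test_b1_block(self, conditional_instance):
        ds, work, st, pri = conditional_instance
        Re_inv = np.linalg.inv(st.Re)
        St_inv = np.linalg.inv(st.Sigma_t)
        G_inv = np.linalg.inv(work.G)
        Yr = ds.Y - st.beta[work.env_of_row] - st.b2[work.env_of_row * 4 + work.line_of_row]
        Q = np.kron(St_inv, G_inv) + np.kron(Re_inv, work.Z1.T @ work.Z1)
        mean = np.linalg.solve(Q, _vec(work.Z1.T @ Yr @ Re_inv))
        cov = np.linalg.inv(Q)
        emp_mean, emp_cov, n = _empirical_moments(
            gibbs_step_b1, st, work, pri, "b1")
        tol = 5 * np.sqrt(np.diag(cov).max() / n)
        assert np.abs(emp_mean - mean).max() < tol
        assert np.abs(emp_cov - cov).max() < 12 * np.diag(cov).max() / np.sqrt(n)

    def test_b2_block(self, conditional_instance):
        ds, work, st, pri = conditional_instance
        Re_inv = np.linalg.inv(st.Re)
        St_inv = np.linalg.inv(st.Sigma_t)
        K_inv = np.linalg.inv(np.kron(st.Sigma_E, work.G))
        Yr = ds.Y - st.beta[work.env_of_row] - st.b1[work.line_of_row]
        Q = np.kron(St_inv, K_inv) + np.kron(Re_inv, work.Z2.T @ work.Z2)
        mean = np.linalg.solve(Q, _vec(work.Z2.T @ Yr @ Re_inv))
        cov = np.linalg.inv(Q)
        emp_mean, emp_cov, n = _empirical_moments(
            gibbs_step_b2, st, work, pri, "b2")
        tol = 5 * np.sqrt(np.diag(cov).max() / n)
        assert np.abs(emp_mean - mean).max() < tol
        assert np.abs(emp_cov - cov).max() < 12 * np.diag(cov).max() / np.sqrt(n)

    def test_flat_prior_ols_limit(self, conditional_instance):
        """With tiny residual variance and no random effects, the beta
        draw collapses onto the least-squares environment-trait means."""
        ds, work, st, pri = conditional_instance
        st = st.copy()
        st.b1[:] = 0.0
        st.b2[:] = 0.0
        st.Re = 1e-12 * np.eye(2)
        flat = BMTMEPriors(beta_precision=0.0).resolved(2, 2)
        rng = np.random.default_rng(9)
        new = gibbs_step_beta(st, work, flat, rng, Y=ds.Y)
        ols = np.linalg.lstsq(work.X, ds.Y, rcond=None)[0]
        np.testing.assert_allclose(new.beta, ols, atol=1e-4)


class TestInverseWishartConditionals:
    def test_re_conditional_mean(self, conditional_instance):
        """Empirical mean of Re draws matches (S0 + E'E)/(nu0 + n - L - 1)."""
        ds, work, st, pri = conditional_instance
        E = ds.Y - work.fitted(st)
        n, L = ds.Y.shape
        expected = (pri.S_R + E.T @ E) / (pri.nu_R + n - L - 1)
        rng = np.random.default_rng(10)
        draws = np.array([
            gibbs_step_Re(st, work, pri, rng, Y=ds.Y).Re for _ in range(20_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), expected,
                                   rtol=0.05, atol=0.02)

    def test_sigma_t_conditional_mean_pools_b1_and_b2(self, conditional_instance):
        ds, work, st, pri = conditional_instance
        G_inv = np.linalg.inv(work.G)
        K_inv = np.linalg.inv(np.kron(st.Sigma_E, work.G))
        scale = (pri.S_t + st.b1.T @ G_inv @ st.b1
                 + st.b2.T @ K_inv @ st.b2)
        df = pri.nu_t + 4 + 8
        expected = scale / (df - 2 - 1)
        rng = np.random.default_rng(11)
        draws = np.array([
            gibbs_step_sigma_t(st, work, pri, rng).Sigma_t
            for _ in range(20_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), expected,
                                   rtol=0.05, atol=0.02)

    def test_sigma_e_conditional_mean(self, conditional_instance):
        ds, work, st, pri = conditional_instance
        # oracle scale: quadratic form of b2 in Sigma_E, computed densely
        G_inv = np.linalg.inv(work.G)
        St_inv = np.linalg.inv(st.Sigma_t)
        J, I, L = 4, 2, 2
        Q = np.zeros((I, I))
        for l in range(L):
            for m in range(L):
                Vl = st.b2[:, l].reshape(I, J).T
                Vm = st.b2[:, m].reshape(I, J).T
                Q += St_inv[l, m] * (Vl.T @ G_inv @ Vm)
        expected = (pri.S_E + Q) / (pri.nu_E + J * L - I - 1)
        rng = np.random.default_rng(12)
        draws = np.array([
            gibbs_step_sigma_E(st, work, pri, rng).Sigma_E
            for _ in range(20_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), expected,
                                   rtol=0.05, atol=0.02)


class TestRunGibbs:
    def test_identical_seeds_identical_chains(self, small_dataset):
        ds, _ = small_dataset
        a = run_gibbs(ds, n_iter=120, burn_in=60, thin=2, seed=7)
        b = run_gibbs(ds, n_iter=120, burn_in=60, thin=2, seed=7)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_retained_draw_count_and_pd(self, small_dataset):
        ds, _ = small_dataset
        ch = run_gibbs(ds, n_iter=150, burn_in=70, thin=3, seed=1)
        assert ch.n_kept == int(np.ceil((150 - 70) / 3))
        for name in ("Sigma_t", "Sigma_E", "Re"):
            for draw in ch.draws[name]:
                assert np.linalg.eigvalsh(draw).min() > 0

    def test_no_gxe_excludes_sigma_e(self, small_dataset):
        ds, _ = small_dataset
        ch = run_gibbs(ds, include_gxe=False, n_iter=100, burn_in=50, seed=2)
        assert "Sigma_E" not in ch.draws and "b2" not in ch.draws

    def test_without_gxe_residual_variance_inflates(self):
        """Dropping the GxE term pushes its variance into the residual."""
        cfg = SimulationConfig(J=30, I=3, L=2, p=100, include_gxe=True, seed=3,
                               Sigma_E=np.eye(3) * 2.0 + 0.4)
        ds, _ = simulate_dataset(cfg)
        with_g = run_gibbs(ds, include_gxe=True, n_iter=800, burn_in=400, seed=4)
        without = run_gibbs(ds, include_gxe=False, n_iter=800, burn_in=400, seed=4)
        re_with = np.trace(with_g.posterior_mean("Re"))
        re_without = np.trace(without.posterior_mean("Re"))
        assert re_without > re_with

    def test_n_iter_must_exceed_burn_in(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="burn_in"):
            run_gibbs(ds, n_iter=100, burn_in=100)


class TestPredict:
    def test_fixed_effect_only_recovery(self):
        """When Y = X beta exactly, predictions are the environment means."""
        from mtmepred.data import GRM, MTMEDataset

        J, I, L = 8, 2, 2
        lines = [f"L{j}" for j in range(J)]
        envs = ["E1", "E2"]
        beta = np.array([[1.0, -1.0], [4.0, 2.0]])
        Y = np.repeat(beta, J, axis=0)
        cells = [(l, e) for e in envs for l in lines]
        ds = MTMEDataset(cells, Y, envs, ["T1", "T2"], GRM(np.eye(J), lines), lines)
        ch = run_gibbs(ds, n_iter=600, burn_in=300, seed=5)
        preds = predict(ch, ds, cells)
        np.testing.assert_allclose(preds, Y, atol=0.25)

    def test_information_gain_over_env_means(self):
        """On heritable data, predictions for held-out cells correlate with
        the true genetic values better than an environment-mean predictor
        (whose within-environment correlation is zero)."""
        from mtmepred.crossval import cv2_partition
        from mtmepred.simulate import mask_cells

        cfg = SimulationConfig(J=40, I=2, L=2, p=150, seed=6,
                               include_gxe=False, Re=np.eye(2) * 0.2)
        ds, truth = simulate_dataset(cfg)
        part = cv2_partition(ds, 0.2, 1, seed=7)[0]
        masked = mask_cells(ds, part)
        ch = run_gibbs(masked, include_gxe=False, n_iter=800, burn_in=400, seed=8)
        cells = sorted(part.test_cells)
        preds = predict(ch, masked, cells)
        rows = [ds.cell_index(*c) for c in cells]
        gv = truth.genetic_values[rows]
        env_idx = [ds.env_ids.index(e) for _, e in cells]
        obs = masked.observed_mask()
        env_of_row = np.repeat(np.arange(ds.n_envs), ds.n_lines)
        env_means = np.stack([
            np.nanmean(masked.Y[(env_of_row == i) & obs], axis=0)
            for i in range(ds.n_envs)
        ])
        baseline = env_means[env_idx]
        r_model = np.corrcoef(preds[:, 0], gv[:, 0])[0, 1]
        r_baseline = np.corrcoef(baseline[:, 0], gv[:, 0])[0, 1]
        assert r_model > r_baseline
        assert r_model > 0.25

    def test_permutation_equivariance(self, small_dataset):
        ds, _ = small_dataset
        ch = run_gibbs(ds, n_iter=100, burn_in=50, seed=9)
        cells = list(ds.cells)
        preds = predict(ch, ds, cells)
        rev = predict(ch, ds, cells[::-1])
        np.testing.assert_array_equal(preds, rev[::-1])

    def test_unknown_ids_rejected(self, small_dataset):
        ds, _ = small_dataset
        ch = run_gibbs(ds, n_iter=60, burn_in=30, seed=10)
        with pytest.raises(KeyError, match="line"):
            predict(ch, ds, [("nope", ds.env_ids[0])])
        with pytest.raises(KeyError, match="environment"):
            predict(ch, ds, [(ds.line_ids[0], "nope")])


class TestEstimator:
    def test_sklearn_contract(self, small_dataset):
        ds, _ = small_dataset
        est = BMTMERegressor(n_iter=80, burn_in=40, random_state=0)
        params = est.get_params()
        assert params["n_iter"] == 80
        est.set_params(n_iter=100)
        est.fit(ds)
        assert hasattr(est, "chains_")
        assert est.posterior_mean_["Sigma_t"].shape == (2, 2)

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError, match="fit"):
            BMTMERegressor().predict([("a", "b")])
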