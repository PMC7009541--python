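import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neonorm import gp_kernels as gpk


def dense_lml_oracle(X, Y, kernel, coreg, noise_mode="coupled"):
    """Explicit inverse + slogdet on the full stacked covariance."""
    K = gpk.icm_train_covariance(kernel, coreg, X, noise_mode=noise_mode)
    y = Y.T.ravel()
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return -0.5 * y @ np.linalg.solve(K, y) - 0.5 * logdet - 0.5 * y.size * np.log(2 * np.pi)


class TestKernelMatrix:
    def test_single_zero_point(self):
        params = gpk.KernelParams(1.0, 1.0, 1.0, 0.5)
        K = gpk.kernel_matrix(params, np.zeros((1, 3)), include_white=True)
        # linear term of the zero vector is 0, rbf(0) = sigma^2_rbf, plus white
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(1.5)

    def test_rbf_decays_monotonically_to_zero(self):
        params = gpk.KernelParams(0.0, 2.0, 1.0, 0.0)
        x0 = np.zeros((1, 3))
        dists = np.linspace(0, 50, 40)
        vals = [gpk.kernel_matrix(params, x0, np.array([[d, 0, 0]]))[0, 0] for d in dists]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-200 * vals[0] or vals[-1] < 1e-12

    def test_sum_of_three_terms_brute_force(self, rng):
        X = rng.normal(size=(6, 3))
        params = gpk.KernelParams(0.7, 1.3, 0.9, 0.4)
        K = gpk.kernel_matrix(params, X, include_white=True)
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                lin = 0.7 * X[i] @ X[j]
                rbf = 1.3 * np.exp(-0.5 * np.sum(((X[i] - X[j]) / 0.9) ** 2))
                expected[i, j] = lin + rbf + (0.4 if i == j else 0.0)
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_white_on_cross_covariance_rejected(self, rng):
        params = gpk.KernelParams()
        with pytest.raises(ValueError, match="cross"):
            gpk.kernel_matrix(params, rng.normal(size=(3, 3)), rng.normal(size=(2, 3)),
                              include_white=True)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            gpk.kernel_matrix(gpk.KernelParams(), np.array([[np.nan, 0, 0]]))

    def test_ard_lengthscale(self, rng):
        X = rng.normal(size=(5, 3))
        ls = np.array([0.5, 1.0, 2.0])
        params = gpk.KernelParams(0.0, 1.0, ls, 0.0)
        K = gpk.kernel_matrix(params, X)
        i, j = 1, 3
        expected = np.exp(-0.5 * np.sum(((X[i] - X[j]) / ls) ** 2))
        assert K[i, j] == pytest.approx(expected)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_training_matrix_symmetric_psd(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(5, 3))
        params = gpk.KernelParams(*r.uniform(0.1, 2.0, size=3), r.uniform(0.1, 1.0))
        K = gpk.kernel_matrix(params, X, include_white=True)
        assert np.allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-10


class TestICMCovariance:
    def setup_method(self):
        self.kernel = gpk.KernelParams(0.5, 1.0, 1.0, 0.3)

    def test_identity_B_zeroes_cross_output_entries(self, rng):
        coreg = gpk.CoregionalizationParams.identity(5)
        X = rng.normal(size=(2, 3))
        K = gpk.icm_covariance(self.kernel, coreg, X, [0, 3])
        assert K[0, 1] == 0.0
        assert K[1, 0] == 0.0
        assert K[0, 0] != 0.0

    def test_all_ones_B_collapses_outputs(self, rng):
        # B = J: one shared function, K((x,i),(x',j)) = k(x,x') for all i,j
        coreg = gpk.CoregionalizationParams(np.ones((5, 1)), np.zeros(5))
        X = rng.normal(size=(4, 3))
        idx = np.array([0, 1, 2, 3])
        K = gpk.icm_covariance(self.kernel, coreg, X, idx)
        np.testing.assert_allclose(K, gpk.kernel_matrix(self.kernel, X), atol=1e-12)

    def test_kronecker_oracle(self, rng):
        W = rng.normal(size=(5, 2))
        kappa = rng.uniform(0.1, 1.0, 5)
        coreg = gpk.CoregionalizationParams(W, kappa)
        X = rng.normal(size=(4, 3))
        # output-major stacking: all points of output 0, then output 1, ...
        Xs = np.tile(X, (5, 1))
        idx = np.repeat(np.arange(5), 4)
        K = gpk.icm_covariance(self.kernel, coreg, Xs, idx)
        expected = np.kron(coreg.B, gpk.kernel_matrix(self.kernel, X))
        np.testing.assert_allclose(K, expected, atol=1e-10)

    def test_output_index_out_of_range(self, rng):
        coreg = gpk.CoregionalizationParams.identity(5)
        with pytest.raises(ValueError, match="output indices"):
            gpk.icm_covariance(self.kernel, coreg, rng.normal(size=(2, 3)), [0, 5])

    def test_train_covariance_matches_explicit_dense(self, rng):
        coreg = gpk.CoregionalizationParams(rng.normal(size=(5, 2)), rng.uniform(0.1, 1, 5))
        X = rng.normal(size=(3, 3))
        K = gpk.icm_train_covariance(self.kernel, coreg, X, noise_mode="coupled")
        B = coreg.B
        n = 3
        expected = np.empty((15, 15))
        for a in range(15):
            for b in range(15):
                i, p = divmod(a, n)
                j, q = divmod(b, n)
                k = gpk.kernel_matrix(self.kernel, X[p : p + 1], X[q : q + 1])[0, 0]
                expected[a, b] = B[i, j] * (k + (self.kernel.white_variance if p == q else 0))
        np.testing.assert_allclose(K, expected, atol=1e-10)


class TestLogMarginalLikelihood:
    def test_scalar_gaussian_oracle(self):
        # single point, single output, y=2, total k(x,x)=v
        v = 1.7
        kernel = gpk.KernelParams(0.0, 1.2, 1.0, 0.5)  # rbf(0) + white = 1.7
        coreg = gpk.CoregionalizationParams.identity(1)
        lml = gpk.log_marginal_likelihood(np.zeros((1, 3)), np.array([[2.0]]), kernel, coreg)
        expected = -0.5 * 4.0 / v - 0.5 * np.log(2 * np.pi * v)
        assert lml == pytest.approx(expected, abs=1e-10)

    def test_zero_data_leaves_only_logdet_term(self, rng):
        X = rng.normal(size=(4, 3))
        kernel = gpk.KernelParams(0.3, 0.8, 1.1, 0.2)
        coreg = gpk.CoregionalizationParams(rng.normal(size=(3, 1)), rng.uniform(0.1, 1, 3))
        Y = np.zeros((4, 3))
        lml = gpk.log_marginal_likelihood(X, Y, kernel, coreg)
        K = gpk.icm_train_covariance(kernel, coreg, X)
        _, logdet = np.linalg.slogdet(K)
        assert lml == pytest.approx(-0.5 * logdet - 0.5 * 12 * np.log(2 * np.pi), abs=1e-8)

    @pytest.mark.parametrize("noise_mode", ["coupled", "independent"])
    def test_matches_dense_solve_oracle(self, rng, noise_mode):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 2))
        kernel = gpk.KernelParams(0.4, 0.9, 1.3, 0.35)
        coreg = gpk.CoregionalizationParams(rng.normal(size=(2, 2)), rng.uniform(0.2, 1, 2))
        lml = gpk.log_marginal_likelihood(X, Y, kernel, coreg, noise_mode=noise_mode)
        assert lml == pytest.approx(dense_lml_oracle(X, Y, kernel, coreg, noise_mode), abs=1e-8)

    def test_degenerate_B_raises_numerical_error(self, rng):
        kernel = gpk.KernelParams(0.0, 0.0, 1.0, 0.0)
        coreg = gpk.CoregionalizationParams(np.zeros((2, 1)), np.zeros(2))  # B = 0
        with pytest.raises(gpk.NumericalError):
            gpk.log_marginal_likelihood(rng.normal(size=(3, 3)), rng.normal(size=(3, 2)),
                                        kernel, coreg)


class TestOptimizeHyperparameters:
    def test_pure_noise_shrinks_rbf(self):
        r = np.random.default_rng(0)
        X = np.column_stack([r.uniform(37, 45, 100), r.uniform(30, 42, 100),
                             r.integers(0, 2, 100)])
        X[:, 1] = np.minimum(X[:, 1], X[:, 0])
        Y = r.normal(0.0, 1.0, size=(100, 2))
        fit = gpk.optimize_hyperparameters(X, Y, n_restarts=2, seed=0, rank=1)
        assert fit.kernel.rbf_variance <= 0.1 * fit.kernel.white_variance

    def test_reoptimization_is_a_fixed_point(self, rng):
        X = rng.normal(size=(20, 3))
        Y = np.sin(X[:, :1]) + 0.1 * rng.normal(size=(20, 2))
        fit = gpk.optimize_hyperparameters(X, Y, n_restarts=2, seed=1, rank=1, maxiter=500)
        refit = gpk.optimize_hyperparameters(
            X, Y, init=(fit.kernel, fit.coreg), n_restarts=1, seed=1, rank=1, maxiter=500
        )
        assert abs(refit.lml - fit.lml) < 1e-6

    def test_returned_lml_dominates_generating_params(self):
        r = np.random.default_rng(3)
        n, m = 60, 3
        X = r.normal(size=(n, 3))
        kernel_true = gpk.KernelParams(0.2, 1.0, 1.0, 0.3)
        coreg_true = gpk.CoregionalizationParams(r.normal(size=(m, 1)), np.full(m, 0.3))
        K = gpk.icm_train_covariance(kernel_true, coreg_true, X)
        y = np.linalg.cholesky(K) @ r.normal(size=n * m)
        Y = y.reshape(m, n).T
        fit = gpk.optimize_hyperparameters(X, Y, n_restarts=2, seed=0, rank=1,
                                           standardize=False)
        lml_true = gpk.log_marginal_likelihood(X, Y, kernel_true, coreg_true)
        assert fit.lml >= lml_true - 1e-6

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(15, 3))
        Y = rng.normal(size=(15, 2))
        f1 = gpk.optimize_hyperparameters(X, Y, n_restarts=3, seed=42, rank=1)
        f2 = gpk.optimize_hyperparameters(X, Y, n_restarts=3, seed=42, rank=1)
        assert f1.lml == f2.lml
        assert f1.kernel == f2.kernel

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            gpk.optimize_hyperparameters(rng.normal(size=(2, 3)), rng.normal(size=(2, 2)))


class TestPredict:
    def make_fit(self, rng, n=8, m=3, white=0.3):
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, m))
        kernel = gpk.KernelParams(0.4, 1.0, 1.2, white)
        coreg = gpk.CoregionalizationParams(rng.normal(size=(m, 2)) * 0.6,
                                            rng.uniform(0.2, 0.8, m))
        fit = gpk.MOGPFit(
            kernel=kernel, coreg=coreg, X=X, Y=Y,
            input_loc=np.zeros(3), input_scale=np.ones(3),
            output_means=np.zeros(m), output_scales=np.ones(m),
        )
        return fit.finalize()

    def test_interpolation_limit(self, rng):
        fit = self.make_fit(rng, white=1e-9)
        mean, _ = gpk.predict(fit, fit.X[2:3], include_noise=False)
        np.testing.assert_allclose(mean[0], fit.Y[2], atol=1e-4)

    def test_noise_share_is_constant_offset(self, rng):
        fit = self.make_fit(rng)
        Xq = rng.normal(size=(4, 3))
        _, v_lat = gpk.predict(fit, Xq, include_noise=False)
        _, v_full = gpk.predict(fit, Xq, include_noise=True)
        diff = v_full - v_lat
        expected = fit.kernel.white_variance * np.diag(fit.coreg.B)
        np.testing.assert_allclose(diff, np.tile(expected, (4, 1)), atol=1e-10)
        assert np.all(v_lat > 0)

    def test_closed_form_oracle(self, rng):
        fit = self.make_fit(rng, n=8, m=3)
        Xq = rng.normal(size=(3, 3))
        mean, var = gpk.predict(fit, Xq, include_noise=False)
        K = gpk.icm_train_covariance(fit.kernel, fit.coreg, fit.X)
        y = fit.Y.T.ravel()
        B = fit.coreg.B
        for t in range(3):
            kvec = gpk.kernel_matrix(fit.kernel, fit.X, Xq[t : t + 1]).ravel()
            for c in range(3):
                cross = np.concatenate([B[c, j] * kvec for j in range(3)])
                mu = cross @ np.linalg.solve(K, y)
                kss = (fit.kernel.linear_variance * Xq[t] @ Xq[t]
                       + fit.kernel.rbf_variance)
                v = B[c, c] * kss - cross @ np.linalg.solve(K, cross)
                assert mean[t, c] == pytest.approx(mu, abs=1e-8)
                assert var[t, c] == pytest.approx(v, abs=1e-8)

    def test_block_independence_with_identity_B(self, rng):
        # ICM with B=I and a shared kernel reproduces independent per-output GPs
        n, m = 10, 5
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, m))
        kernel = gpk.KernelParams(0.3, 0.9, 1.1, 0.25)
        joint = gpk.MOGPFit(
            kernel=kernel, coreg=gpk.CoregionalizationParams.identity(m),
            X=X, Y=Y, input_loc=np.zeros(3), input_scale=np.ones(3),
            output_means=np.zeros(m), output_scales=np.ones(m),
        ).finalize()
        Xq = rng.normal(size=(4, 3))
        mean_joint, var_joint = gpk.predict(joint, Xq, include_noise=True)
        for c in range(m):
            single = gpk.MOGPFit(
                kernel=kernel, coreg=gpk.CoregionalizationParams.identity(1),
                X=X, Y=Y[:, c : c + 1], input_loc=np.zeros(3), input_scale=np.ones(3),
                output_means=np.zeros(1), output_scales=np.ones(1),
            ).finalize()
            mean_c, var_c = gpk.predict(single, Xq, output_index=0, include_noise=True)
            np.testing.assert_allclose(mean_joint[:, c], mean_c, atol=1e-6)
            np.testing.assert_allclose(var_joint[:, c], var_c, atol=1e-6)

    def test_variance_shrinks_when_training_point_added_at_query(self, rng):
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 2))
        xq = rng.normal(size=(1, 3))
        kernel = gpk.KernelParams(0.3, 1.0, 1.0, 0.2)
        coreg = gpk.CoregionalizationParams(rng.normal(size=(2, 1)), np.array([0.3, 0.3]))

        def make(Xt, Yt):
            return gpk.MOGPFit(
                kernel=kernel, coreg=coreg, X=Xt, Y=Yt,
                input_loc=np.zeros(3), input_scale=np.ones(3),
                output_means=np.zeros(2), output_scales=np.ones(2),
            ).finalize()

        _, v_before = gpk.predict(make(X, Y), xq, include_noise=False)
        X2 = np.vstack([X, xq])
        Y2 = np.vstack([Y, rng.normal(size=(1, 2))])
        _, v_after = gpk.predict(make(X2, Y2), xq, include_noise=False)
        assert np.all(v_after <= v_before + 1e-10)

    def test_affine_equivariance_of_standardization(self, rng):
        # fitting standardized data manually and de-standardizing predictions
        # must equal the built-in standardize=True path
        n = 25
        X = np.column_stack([rng.uniform(37, 45, n), rng.uniform(30, 42, n),
                             rng.integers(0, 2, n).astype(float)])
        X[:, 1] = np.minimum(X[:, 1], X[:, 0])
        Y = np.column_stack([3 * X[:, 0] + rng.normal(size=n),
                             50 + rng.normal(size=n) * 2])
        fit_auto = gpk.optimize_hyperparameters(X, Y, n_restarts=1, seed=5, rank=1)

        Xs, loc, scale = gpk.standardize_inputs(X)
        ym, ysd = Y.mean(axis=0), Y.std(axis=0)
        Ys = (Y - ym) / ysd
        fit_manual = gpk.optimize_hyperparameters(Xs, Ys, n_restarts=1, seed=5, rank=1,
                                                  standardize=False)
        Xq = np.array([[40.0, 38.0, 1.0], [43.0, 33.0, 0.0]])
        mean_auto, var_auto = gpk.predict(fit_auto, Xq)
        mean_man, var_man = gpk.predict(fit_manual, (Xq - loc) / scale)
        np.testing.assert_allclose(mean_auto, mean_man * ysd + ym, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(var_auto, var_man * ysd**2, rtol=1e-6, atol=1e-8)


class TestSerialization:
    def test_round_trip_predictions_identical(self, rng):
        X = rng.normal(size=(12, 3))
        Y = rng.normal(size=(12, 5))
        fit = gpk.optimize_hyperparameters(X, Y, n_restarts=1, seed=0)
        clone = gpk.MOGPFit.from_dict(fit.to_dict())
        Xq = rng.normal(size=(3, 3))
        m1, v1 = gpk.predict(fit, Xq)
        m2, v2 = gpk.predict(clone, Xq)
        np.testing.assert_allclose(m1, m2, atol=1e-12)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    @pytest.mark.parametrize("rank", [1, 2, 5])
    def test_ranks_supported(self, rng, rank):
        X = rng.normal(size=(15, 3))
        Y = rng.normal(size=(15, 5)) + np.sin(X[:, :1])
        fit = gpk.optimize_hyperparameters(X, Y, n_restarts=1, seed=0, rank=rank, maxiter=60)
        assert fit.coreg.rank == rank
        assert np.isfinite(fit.lml)
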