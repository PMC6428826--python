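"""Noise-model estimators, whitening transforms and the pre-whitened GLM."""

import numpy as np
import pytest
from scipy import linalg, stats

import prewhiten as pw
from prewhiten.whiten import (arma_acf, arma_profile_loglik, sample_acf,
                              tukey_window, unwhitened_task_selection)


def dense_reml_loglik(resid, a, b, X=None):
    """Oracle: the same (RE)ML profile likelihood via dense Cholesky of the
    closed-form ARMA covariance (independent of the banded-filter route)."""
    R = np.atleast_2d(resid)
    T = R.shape[1]
    g0 = (1 + 2 * a * b + b * b) / (1 - a * a)
    V = linalg.toeplitz(arma_acf(a, b, T)) * g0
    L = linalg.cholesky(V, lower=True)
    logdet = 2 * np.log(np.diag(L)).sum()
    Vi = linalg.inv(V)
    if X is None:
        q = np.einsum("vt,tu,vu->v", R, Vi, R)
        return -0.5 * logdet - 0.5 * T * np.log(q / T)
    G = X.T @ Vi @ X
    _, logdet_g = np.linalg.slogdet(G)
    A = Vi - Vi @ X @ linalg.solve(G, X.T @ Vi)
    q = np.einsum("vt,tu,vu->v", R, A, R)
    df = T - X.shape[1]
    return -0.5 * (logdet + logdet_g) - 0.5 * df * np.log(q / df)


class TestFitOLS:
    def test_data_in_column_space_gives_zero_residuals(self, small_grid,
                                                       boxcar10_design):
        X = boxcar10_design
        rng = np.random.default_rng(0)
        B = rng.standard_normal((20, X.n_columns))
        Y = B @ X.matrix.T
        fit = pw.fit_ols(Y, X)
        assert np.abs(fit.residuals).max() < 1e-8
        np.testing.assert_allclose(fit.coefficients, B, atol=1e-8)

    def test_degrees_of_freedom(self, boxcar10_design):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((10, 225))
        fit = pw.fit_ols(Y, boxcar10_design)
        assert fit.df == 225 - 12 == 213

    def test_residuals_orthogonal_to_design(self, boxcar10_design):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((50, 225))
        fit = pw.fit_ols(Y, boxcar10_design)
        assert np.abs(fit.residuals @ boxcar10_design.matrix).max() < 1e-8

    def test_coefficients_unbiased_under_white_noise(self, boxcar10_design):
        """Mean task-coefficient over 1000 white-noise voxels with injected
        beta=0.5 recovers the truth within the Monte-Carlo CI."""
        rng = np.random.default_rng(3)
        X = boxcar10_design
        task = X.matrix[:, X.column_roles.index("task")]
        Y = 0.5 * task + rng.standard_normal((1000, 225))
        fit = pw.fit_ols(Y, X)
        betas = fit.coefficients @ X.task_contrast
        ci = 3 * betas.std(ddof=1) / np.sqrt(len(betas))
        assert betas.mean() == pytest.approx(0.5, abs=ci)


class TestWhiteningMatrix:
    def test_identity_covariance_gives_identity(self):
        model = pw.identity_model(30)
        np.testing.assert_allclose(pw.build_whitening_matrix(model, 30),
                                   np.eye(30), atol=1e-12)

    def test_defining_property_for_arbitrary_acf(self):
        for acf_gen in (lambda k: 0.6 ** k, lambda k: np.exp(-k / 3.0)):
            acf = acf_gen(np.arange(40).astype(float))
            model = pw.NoiseModel(method="fast", scope="global", acf=acf)
            W = pw.build_whitening_matrix(model, 40)
            V = model.covariance(40)
            np.testing.assert_allclose(W @ V @ W.T, np.eye(40), atol=1e-8)

    def test_ar1_closed_form_rows(self):
        a, T = 0.5, 25
        acf = a ** np.arange(T).astype(float)
        model = pw.NoiseModel(method="spm_ar1wn", scope="global", acf=acf)
        W = pw.build_whitening_matrix(model, T)
        s = 1.0 / np.sqrt(1 - a * a)
        assert W[0, 0] == pytest.approx(1.0, abs=1e-8)
        for i in range(1, T):
            assert W[i, i] == pytest.approx(s, abs=1e-8)
            assert W[i, i - 1] == pytest.approx(-a * s, abs=1e-8)
            if i >= 2:
                assert np.abs(W[i, : i - 1]).max() < 1e-8


class TestARMAGrid:
    def test_banded_likelihood_matches_dense_oracle(self):
        rng = np.random.default_rng(4)
        R = rng.standard_normal((4, 40))
        X = np.column_stack([np.ones(40), np.arange(40.0)])
        for a, b in [(0.0, 0.0), (0.5, -0.2), (-0.3, 0.4), (0.85, 0.1)]:
            np.testing.assert_allclose(
                arma_profile_loglik(R, a, b), dense_reml_loglik(R, a, b),
                rtol=1e-10)
            np.testing.assert_allclose(
                arma_profile_loglik(R, a, b, X=X),
                dense_reml_loglik(R, a, b, X=X), rtol=1e-8)

    def test_grid_point_is_global_argmax(self):
        """Exhaustive check at small T: the likelihood at the returned (a,b)
        is >= the likelihood at every other grid point (dense oracle)."""
        T = 48
        x = pw.gen_noise_timeseries(
            pw.NoiseSpec(kind="arma11", ar_coef=0.5, ma_coef=0.2), T, 2.0, 11)
        grid = pw.GridSpec(nx=1, ny=1, nz=1, n_timepoints=T)
        X = pw.build_design_matrix(None, grid, cutoff_period=1e12)
        fit = pw.fit_ols(x[None, :], X)
        # raw argmax (parsimony guard off) for the pure likelihood property
        model = pw.estimate_afni_arma11(fit, grid_step=0.1, null_lrt_alpha=1)
        a_hat, b_hat = model.params["a"][0], model.params["b"][0]
        ll_hat = dense_reml_loglik(fit.residuals, a_hat, b_hat, X=X.matrix)[0]
        axis = np.arange(-0.9, 0.91, 0.1)
        for a in axis:
            for b in axis:
                ll = dense_reml_loglik(fit.residuals, a, b, X=X.matrix)[0]
                assert ll <= ll_hat + 1e-9

    def test_white_noise_recovers_origin(self, rest_design):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((1000, 225))
        fit = pw.fit_ols(Y, rest_design)
        model = pw.estimate_afni_arma11(fit)
        at_origin = (model.params["a"] == 0) & (model.params["b"] == 0)
        assert at_origin.mean() >= 0.95

    def test_parameters_lie_on_grid(self, rest_design):
        rng = np.random.default_rng(6)
        Y = np.cumsum(rng.standard_normal((20, 225)), axis=1) * 0.1 \
            + rng.standard_normal((20, 225))
        fit = pw.fit_ols(Y, rest_design)
        model = pw.estimate_afni_arma11(fit, grid_step=0.05)
        for arr in (model.params["a"], model.params["b"]):
            np.testing.assert_allclose(arr / 0.05, np.round(arr / 0.05),
                                       atol=1e-9)
            assert np.abs(arr).max() <= 0.9 + 1e-9


class TestTukey:
    def test_window_endpoints(self):
        w = tukey_window(100, 63)
        assert w[0] == 1.0
        assert w[63] == 0.0
        assert np.all(w[63:] == 0)
        assert w[1] == pytest.approx(0.5 * (1 + np.cos(np.pi / 63)))

    def test_acf_zero_beyond_taper(self, rest_design):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((10, 225))
        fit = pw.fit_ols(Y, rest_design)
        model = pw.estimate_fsl_tukey(fit, taper_m=20)
        assert np.all(model.acf[:, 20:] == 0)
        assert np.all(model.acf[:, 0] == 1)

    def test_tapered_lag1_matches_oracle_on_long_series(self):
        """On a long AR(1) a=0.5 series the tapered lag-1 ACF equals the raw
        sample ACF times w(1); the raw estimate is consistent for 0.5."""
        T, M = 10_000, 63
        x = pw.gen_noise_timeseries(pw.NoiseSpec(kind="ar1", ar_coef=0.5),
                                    T, 2.0, 8)
        grid = pw.GridSpec(nx=1, ny=1, nz=1, n_timepoints=T)
        X = pw.build_design_matrix(None, grid, cutoff_period=1e12)
        fit = pw.fit_ols(x[None, :], X)
        model = pw.estimate_fsl_tukey(fit, taper_m=M)
        raw = sample_acf(fit.residuals, 2)[:, 1][0]
        w1 = 0.5 * (1 + np.cos(np.pi / M))
        assert model.acf[0, 1] == pytest.approx(raw * w1, abs=1e-12)
        assert model.acf[0, 1] == pytest.approx(0.5 * w1, abs=0.03)

    def test_invalid_taper_rejected(self, rest_design):
        rng = np.random.default_rng(9)
        fit = pw.fit_ols(rng.standard_normal((5, 225)), rest_design)
        with pytest.raises(ValueError):
            pw.estimate_fsl_tukey(fit, taper_m=225)


class TestSPMGlobal:
    def test_white_noise_gives_near_zero_lag1(self, rest_design):
        rng = np.random.default_rng(10)
        fit = pw.fit_ols(rng.standard_normal((2000, 225)), rest_design)
        model = pw.estimate_spm_ar1wn(fit)
        assert abs(model.acf[1]) < 0.02

    def test_in_family_recovery(self, small_grid, boxcar10_design):
        noise = pw.NoiseSpec(kind="ar1_plus_wn", ar_coef=0.2, wn_fraction=0.3)
        vol = pw.gen_resting_volume(small_grid, noise, seed=21)
        fit = pw.fit_ols(vol, boxcar10_design)
        model = pw.estimate_spm_ar1wn(fit)
        true_lag1 = (1 - 0.3) * 0.2
        assert model.acf[1] == pytest.approx(true_lag1, abs=0.03)
        assert model.scope == "global"

    def test_selection_pooled_over_exact_voxel_set(self, small_grid,
                                                   boxcar10_design):
        """The global fit pools exactly the voxels with unwhitened task
        p < 0.001 (the stated selection rule)."""
        X = boxcar10_design
        rng = np.random.default_rng(22)
        task = X.matrix[:, X.column_roles.index("task")]
        Y = rng.standard_normal((500, 225))
        Y[:40] += 2.0 * task  # strongly responding voxels
        fit = pw.fit_ols(Y, X)
        sel = unwhitened_task_selection(fit, p_threshold=0.001)
        pvals = stats.t.sf(fit.tmap, fit.df)
        np.testing.assert_array_equal(sel, pvals < 0.001)
        assert sel.sum() >= 40
        model = pw.estimate_spm_ar1wn(fit, selection=sel)
        assert model.params["n_selected"] == int(sel.sum())


class TestFAST:
    def test_default_dictionary_has_18_components(self):
        comps = pw.fast_dictionary(225, 2.0, p=6)
        assert len(comps) == 18
        for q in comps:
            assert q.shape == (225, 225)
            np.testing.assert_allclose(q, q.T)

    def test_white_noise_fit_close_to_identity(self, rest_design):
        rng = np.random.default_rng(23)
        fit = pw.fit_ols(rng.standard_normal((3000, 225)), rest_design)
        model = pw.estimate_fast(fit)
        assert np.abs(model.acf[1:]).max() < 0.02
        assert model.params["n_components"] == 18

    def test_exponential_acf_recovery(self, small_grid, rest_design):
        noise = pw.NoiseSpec(kind="exp_acf", exp_tau=4.0)
        vol = pw.gen_resting_volume(small_grid, noise, seed=24)
        fit = pw.fit_ols(vol, rest_design)
        model = pw.estimate_fast(fit)
        true_acf = np.exp(-np.arange(11) * 2.0 / 4.0)
        np.testing.assert_allclose(model.acf[1:11], true_acf[1:], atol=0.05)


class TestPrewhitenedGLM:
    def test_identity_model_reproduces_ols(self, boxcar10_design):
        rng = np.random.default_rng(25)
        Y = rng.standard_normal((100, 225))
        fit0 = pw.fit_ols(Y, boxcar10_design)
        fit1 = pw.prewhitened_glm(Y, boxcar10_design,
                                  pw.identity_model(225))
        np.testing.assert_allclose(fit1.tmap, fit0.tmap)
        np.testing.assert_allclose(fit1.residuals, fit0.residuals)

    def test_gls_variance_matches_formula(self, boxcar10_design):
        """Across 3000 independent AR(1) voxels (acting as replicates), the
        empirical variance of the whitened task coefficient matches
        c'(X'V^{-1}X)^{-1}c."""
        X = boxcar10_design
        T, a = 225, 0.5
        noise = pw.NoiseSpec(kind="ar1", ar_coef=a)
        grid = pw.GridSpec(nx=30, ny=10, nz=10, n_timepoints=T)
        vol = pw.gen_resting_volume(grid, noise, seed=26)
        acf = noise.theoretical_acf(T, 2.0)
        model = pw.NoiseModel(method="spm_ar1wn", scope="global", acf=acf)
        fit = pw.prewhitened_glm(vol, X, model)
        V = linalg.toeplitz(acf)
        c = X.task_contrast
        expect = c @ linalg.inv(X.matrix.T @ linalg.inv(V) @ X.matrix) @ c
        betas = fit.coefficients @ c
        assert betas.var(ddof=1) == pytest.approx(expect, rel=0.15)

    def test_voxelwise_whitening_batches_match_global(self, boxcar10_design):
        """A voxelwise model whose rows share one ACF gives the same fit as
        the equivalent global model."""
        rng = np.random.default_rng(27)
        Y = rng.standard_normal((40, 225))
        acf = 0.4 ** np.arange(225).astype(float)
        g = pw.NoiseModel(method="spm_ar1wn", scope="global", acf=acf)
        v = pw.NoiseModel(method="fsl_tukey", scope="voxelwise",
                          acf=np.tile(acf, (40, 1)))
        fg = pw.prewhitened_glm(Y, boxcar10_design, g)
        fv = pw.prewhitened_glm(Y, boxcar10_design, v)
        np.testing.assert_allclose(fv.tmap, fg.tmap, atol=1e-8)


class TestTToZ:
    def test_zero_maps_to_zero(self):
        assert pw.t_to_z(np.array([0.0]), 10)[0] == 0.0

    def test_large_df_asymptotic_identity(self):
        assert pw.t_to_z(np.array([2.5]), 1e6)[0] == pytest.approx(2.5,
                                                                   abs=1e-3)

    def test_matches_direct_quantile_oracle(self):
        # independent route: plain (non-log) cdf/ppf composition
        for t, df in [(3.09, 100), (1.5, 20), (-2.2, 50), (4.0, 213)]:
            expect = stats.norm.ppf(stats.t.cdf(t, df))
            assert pw.t_to_z(np.array([t]), df)[0] == pytest.approx(expect,
                                                                    abs=1e-10)

    def test_strictly_increasing_and_sign_preserving(self):
        t = np.linspace(-30, 30, 301)
        z = pw.t_to_z(t, 60)
        assert np.all(np.diff(z) > 0)
        assert np.all(np.sign(z) == np.sign(t))
        assert np.isfinite(z).all()

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            pw.t_to_z(np.array([1.0]), 0)
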