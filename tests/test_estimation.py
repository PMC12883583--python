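import numpy as np
import pytest
from scipy.stats import multivariate_normal

from riclpm.estimation import (
    FitOptions,
    PatternStats,
    baseline_loglik,
    fiml_loglik,
    fit,
    fit_to_moments,
    saturated_and_baseline_loglik,
    saturated_loglik,
    standardized_names,
    standardized_vector,
)
from riclpm.model import RICLPMParams, build_riclpm, implied_moments
from riclpm.preprocess import ModelPanel
from riclpm.synthetic import MissingSpec, simulate_panel


def _rowwise_loglik(mu, Sigma, X):
    """Brute-force oracle: each row's observed sub-vector gets its own
    marginal Gaussian density."""
    total = 0.0
    for row in X:
        obs = ~np.isnan(row)
        if not obs.any():
            continue
        total += multivariate_normal.logpdf(
            row[obs], mean=mu[obs], cov=Sigma[np.ix_(obs, obs)]
        )
    return total


class TestFimlLoglik:
    def test_complete_data_equals_direct_gaussian_loglik(self, truth):
        panel = simulate_panel(truth.model_scale(), n=80, seed=1)
        mu, Sigma = implied_moments(truth.params)
        direct = multivariate_normal.logpdf(panel.values, mean=mu, cov=Sigma).sum()
        assert fiml_loglik(truth.params, panel.values) == pytest.approx(direct, abs=1e-10)

    def test_single_observed_variable_contributes_univariate_density(self, truth, schedule):
        X = np.full((1, 12), np.nan)
        X[0, 3] = 0.6
        mu, Sigma = implied_moments(truth.params)
        expected = multivariate_normal.logpdf([0.6], mean=[mu[3]], cov=Sigma[3, 3])
        assert fiml_loglik(truth.params, X) == pytest.approx(float(expected), abs=1e-12)

    def test_pattern_grouped_total_equals_rowwise_oracle(self, truth):
        panel = simulate_panel(truth.model_scale(), n=50,
                               missing=MissingSpec.alspac_like(mechanism="mcar"), seed=4)
        mu, Sigma = implied_moments(truth.params)
        oracle = _rowwise_loglik(mu, Sigma, panel.values)
        assert fiml_loglik(truth.params, panel.values) == pytest.approx(oracle, abs=1e-10)

    def test_all_missing_rows_contribute_nothing(self, truth):
        panel = simulate_panel(truth.model_scale(), n=30, seed=6)
        X = panel.values.copy()
        X[:5] = np.nan
        stats = PatternStats.from_matrix(X)
        assert stats.n == 25 and stats.n_empty == 5
        assert fiml_loglik(truth.params, X) == pytest.approx(
            fiml_loglik(truth.params, X[5:]), abs=1e-10)

    def test_singular_implied_covariance_gives_minus_inf(self, truth):
        p = truth.params
        degenerate = RICLPMParams(psi=np.zeros((2, 2)),
                                  theta1=np.zeros((2, 2)),
                                  B=p.B, theta=p.theta, mu=p.mu)
        X = np.zeros((3, 12))
        assert fiml_loglik(degenerate, X) == -np.inf


class TestFit:
    def test_moment_fit_recovers_truth_exactly(self, truth, index6):
        # n -> infinity trick: the truth's implied moments as pseudo-sample
        mu, Sigma = implied_moments(truth.params)
        res = fit_to_moments(index6, mu, Sigma, n=100_000)
        assert res.converged
        np.testing.assert_allclose(res.x, index6.pack(truth.params), atol=1e-6)

    def test_fit_flags_nonconvergence_but_keeps_output(self, truth, index6,
                                                       model_scale_panel):
        # an unattainable gradient tolerance forces the non-convergence path
        options = FitOptions(se="none", maxiter=1, retries=0, grad_tol=0.0)
        res = fit(index6, PatternStats.from_matrix(model_scale_panel.values), options)
        assert not res.converged
        assert res.params is not None and np.isfinite(res.loglik)

    def test_converged_fit_has_small_gradient(self, truth, index6, model_scale_panel):
        res = fit(index6, PatternStats.from_matrix(model_scale_panel.values),
                  FitOptions(se="none"))
        assert res.converged
        assert res.grad_norm < 1e-5


class TestStandardize:
    def test_unit_within_variances_leave_coefficients_unchanged(self):
        T = 4
        B = np.zeros((T - 1, 2, 2))
        B[:, 0, 1] = 0.25
        theta1 = np.eye(2)
        # innovations chosen so every within variance stays exactly 1
        theta = np.stack([np.eye(2) - B[t] @ np.eye(2) @ B[t].T for t in range(T - 1)])
        params = RICLPMParams(psi=np.zeros((2, 2)), theta1=theta1, B=B, theta=theta,
                              mu=np.zeros(2 * T))
        idx = build_riclpm(T)
        sv = standardized_vector(idx, idx.pack(params))
        names = standardized_names(idx, ("a", "b"))
        for t in range(1, T):
            assert dict(zip(names, sv))[f"cl_b_to_a[{t}]"] == pytest.approx(0.25, abs=1e-10)

    def test_zero_coefficient_standardizes_to_zero(self, truth, index6):
        p = truth.params
        B = p.B.copy()
        B[2, 0, 1] = 0.0
        params = RICLPMParams(psi=p.psi, theta1=p.theta1, B=B, theta=p.theta, mu=p.mu)
        sv = standardized_vector(index6, index6.pack(params))
        names = standardized_names(index6, ("dep", "cm"))
        assert dict(zip(names, sv))["cl_cm_to_dep[3]"] == 0.0

    def test_invariance_under_common_per_construct_rescaling(self, truth, index6):
        # the RI-CLPM with unit loadings is closed under one affine map per
        # construct (applied to every wave); standardized estimates must agree
        panel = simulate_panel(truth.model_scale(), n=500, seed=31)
        X = panel.values
        Y = X.copy()
        Y[:, 0::2] = 3.7 * Y[:, 0::2] - 1.2
        Y[:, 1::2] = 0.4 * Y[:, 1::2] + 5.0
        res_x = fit(index6, PatternStats.from_matrix(X), FitOptions(se="none"))
        res_y = fit(index6, PatternStats.from_matrix(Y), FitOptions(se="none"))
        assert res_x.converged and res_y.converged
        np.testing.assert_allclose(
            standardized_vector(index6, res_x.x),
            standardized_vector(index6, res_y.x), atol=1e-6)


@pytest.fixture(scope="module")
def big_fit(truth, index6):
    panel = simulate_panel(truth.model_scale(), n=10_000, seed=41)
    stats = PatternStats.from_matrix(panel.values)
    robust = fit(index6, stats, FitOptions(se="robust"))
    observed = fit(index6, stats, FitOptions(se="observed"))
    return robust, observed


class TestRobustSE:
    def test_robust_close_to_observed_under_correct_specification(self, big_fit):
        robust, observed = big_fit
        ratio = robust.std_se / observed.std_se
        assert np.all(ratio > 0.85) and np.all(ratio < 1.15)

    def test_ci_halfwidth_is_1p96_se(self, big_fit):
        robust, _ = big_fit
        paths = robust.paths()
        np.testing.assert_allclose(paths["ci_high"] - paths["beta"],
                                   1.96 * paths["se"], atol=1e-12)

    def test_se_scales_as_inverse_root_n(self, truth, index6):
        ses = []
        for n, seed in [(1000, 51), (4000, 51)]:
            panel = simulate_panel(truth.model_scale(), n=n, seed=seed)
            res = fit(index6, PatternStats.from_matrix(panel.values),
                      FitOptions(se="robust"))
            ses.append(np.median(res.std_se[:20]))
        assert ses[0] / ses[1] == pytest.approx(2.0, abs=0.4)


class TestSaturatedAndBaseline:
    def test_complete_data_saturated_is_sample_moments(self, model_scale_panel):
        X = model_scale_panel.values
        ll, mu, Sigma = saturated_loglik(X)
        np.testing.assert_allclose(mu, X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(Sigma, np.cov(X.T, bias=True), atol=1e-10)
        direct = multivariate_normal.logpdf(X, mean=mu, cov=Sigma).sum()
        assert ll == pytest.approx(direct, rel=1e-10)

    def test_missing_data_saturated_beats_any_structured_model(self, truth, index6):
        panel = simulate_panel(truth.model_scale(), n=400,
                               missing=MissingSpec.alspac_like(mechanism="mcar"),
                               seed=8)
        stats = PatternStats.from_matrix(panel.values)
        ll_sat, ll_base, df_base = saturated_and_baseline_loglik(stats)
        assert df_base == 66
        assert ll_base <= ll_sat
        res = fit(index6, stats, FitOptions(se="none"))
        assert res.loglik <= ll_sat + 1e-6

    def test_baseline_matches_univariate_ml(self, model_scale_panel):
        X = model_scale_panel.values
        ll, df_base = baseline_loglik(X)
        expected = 0.0
        for j in range(X.shape[1]):
            col = X[:, j]
            var = col.var()
            expected += multivariate_normal.logpdf(col, mean=col.mean(), cov=var).sum()
        assert ll == pytest.approx(expected, rel=1e-10)
        assert df_base == 66
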