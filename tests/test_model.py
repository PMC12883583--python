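import numpy as np
import pytest

from riclpm.model import (
    ALTSRParams,
    NotIdentifiedError,
    RICLPMParams,
    altsr_df,
    build_altsr,
    build_riclpm,
    implied_moments,
    model_df,
    within_covariance,
)
from riclpm.synthetic import simulate_panel


class TestCounting:
    @pytest.mark.parametrize("T,expected", [(6, 53), (3, 26)])
    def test_riclpm_free_parameter_count(self, T, expected):
        assert build_riclpm(T).n_free == expected

    @pytest.mark.parametrize("T,expected", [(6, 37), (3, 1)])
    def test_model_degrees_of_freedom(self, T, expected):
        assert model_df(T) == expected

    def test_two_waves_not_identified(self):
        with pytest.raises(NotIdentifiedError):
            model_df(2)
        with pytest.raises(NotIdentifiedError):
            build_riclpm(2)

    def test_altsr_counts_and_identification(self, schedule):
        idx = build_altsr(6, schedule)
        # RI-CLPM count + 7 extra covariance entries (2 slope variances,
        # 1 slope-slope, 4 intercept-slope); slope means stay fixed at zero
        # because free per-variable means would absorb them
        assert idx.n_free == 53 + 7
        assert idx.df == 30
        structured = build_altsr(6, schedule, means_mode="structured")
        assert structured.n_free == 52
        assert altsr_df(6, "structured") == 38
        with pytest.raises(NotIdentifiedError):
            build_altsr(3, schedule)


class TestPackUnpack:
    def test_roundtrip_is_identity_on_valid_parameters(self, truth, index6):
        x = index6.pack(truth.params)
        again = index6.pack(index6.unpack(x))
        np.testing.assert_allclose(again, x, atol=1e-12)

    def test_random_vectors_roundtrip_through_unpack(self, index6):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(scale=0.5, size=index6.n_free)
            params = index6.unpack(x)
            np.testing.assert_allclose(index6.pack(params), x, atol=1e-10)

    def test_altsr_roundtrip(self, schedule):
        idx = build_altsr(6, schedule)
        rng = np.random.default_rng(9)
        x = rng.normal(scale=0.3, size=idx.n_free)
        np.testing.assert_allclose(idx.pack(idx.unpack(x)), x, atol=1e-10)


def _univariate_params(a=0.5, v1=1.0, innov=0.75, T=3):
    """One live construct (index 1); the other is frozen near zero."""
    eps = 1e-10
    theta1 = np.diag([eps, v1])
    B = np.zeros((T - 1, 2, 2))
    B[:, 1, 1] = a
    theta = np.stack([np.diag([eps, innov])] * (T - 1))
    return RICLPMParams(psi=np.zeros((2, 2)), theta1=theta1, B=B,
                        theta=theta, mu=np.zeros(2 * T))


class TestImpliedMoments:
    def test_independence_case_is_block_diagonal(self, truth):
        p = truth.params
        params = RICLPMParams(psi=np.zeros((2, 2)), theta1=p.theta1,
                              B=np.zeros_like(p.B), theta=p.theta, mu=p.mu)
        _, Sigma = implied_moments(params)
        for t in range(6):
            for s in range(6):
                blk = Sigma[2 * t:2 * t + 2, 2 * s:2 * s + 2]
                if t != s:
                    np.testing.assert_allclose(blk, 0.0, atol=1e-14)
        np.testing.assert_allclose(Sigma[0:2, 0:2], p.theta1, atol=1e-14)
        np.testing.assert_allclose(Sigma[2:4, 2:4], p.theta[0], atol=1e-14)

    def test_univariate_ar_recursion_by_hand(self):
        # a = 0.5, stationary innovations 0.75: variances 1, lag-1 cov 0.5,
        # lag-2 cov 0.25 by the hand recursion
        _, Sigma = implied_moments(_univariate_params())
        idx = [1, 3, 5]
        sub = Sigma[np.ix_(idx, idx)]
        np.testing.assert_allclose(np.diag(sub), [1.0, 1.0, 1.0], atol=1e-8)
        assert sub[0, 1] == pytest.approx(0.5, abs=1e-8)
        assert sub[1, 2] == pytest.approx(0.5, abs=1e-8)
        assert sub[0, 2] == pytest.approx(0.25, abs=1e-8)

    def test_intercept_variance_shifts_same_construct_covariances(self, truth):
        p = truth.params
        tau = 0.37
        base = RICLPMParams(psi=np.zeros((2, 2)), theta1=p.theta1, B=p.B,
                            theta=p.theta, mu=p.mu)
        bump = RICLPMParams(psi=np.array([[tau, 0.0], [0.0, 0.0]]), theta1=p.theta1,
                            B=p.B, theta=p.theta, mu=p.mu)
        _, S0 = implied_moments(base)
        _, S1 = implied_moments(bump)
        diff = S1 - S0
        expected = np.zeros_like(diff)
        expected[0::2, 0::2] = tau
        np.testing.assert_allclose(diff, expected, atol=1e-12)

    def test_symmetric_and_positive_definite(self, truth):
        _, Sigma = implied_moments(truth.params)
        np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-15)
        assert np.linalg.eigvalsh(Sigma).min() > 0

    def test_monte_carlo_agreement_with_simulator(self, truth):
        mu, Sigma = implied_moments(truth.params)
        panel = simulate_panel(truth.model_scale(), n=100_000, seed=17)
        emp_mu = panel.values.mean(axis=0)
        emp_cov = np.cov(panel.values.T)
        np.testing.assert_allclose(emp_mu, mu, atol=0.002)
        np.testing.assert_allclose(emp_cov, Sigma, atol=6e-4)


class TestALTSR:
    def test_slope_loadings_are_years_since_first_wave(self, schedule):
        idx = build_altsr(6, schedule)
        np.testing.assert_allclose(idx.slope_loadings[0],
                                   [0.0, 2.2, 3.2, 6.0, 7.2, 13.2])
        np.testing.assert_allclose(idx.slope_loadings[1],
                                   [0.0, 2.0, 4.0, 5.6, 8.0, 14.7])

    def test_zero_slope_variance_reduces_to_riclpm(self, truth, schedule):
        p = truth.params
        phi = np.zeros((4, 4))
        phi[:2, :2] = p.psi
        alt = ALTSRParams(phi=phi, theta1=p.theta1, B=p.B, theta=p.theta,
                          slope_loadings=build_altsr(6, schedule).slope_loadings,
                          mu=p.mu)
        mu_a, S_a = implied_moments(alt)
        mu_r, S_r = implied_moments(p)
        np.testing.assert_allclose(mu_a, mu_r, atol=1e-14)
        np.testing.assert_allclose(S_a, S_r, atol=1e-14)

    def test_slope_variance_grows_late_wave_variance(self, truth, schedule):
        p = truth.params
        idx = build_altsr(6, schedule)
        phi = np.zeros((4, 4))
        phi[:2, :2] = p.psi
        phi[2, 2] = phi[3, 3] = 1e-4
        alt = ALTSRParams(phi=phi, theta1=p.theta1, B=p.B, theta=p.theta,
                          slope_loadings=idx.slope_loadings, mu=p.mu)
        _, S_a = implied_moments(alt)
        _, S_r = implied_moments(p)
        growth = np.diag(S_a) - np.diag(S_r)
        lam = idx.slope_loadings
        np.testing.assert_allclose(growth[0::2], 1e-4 * lam[0] ** 2, atol=1e-12)
        np.testing.assert_allclose(growth[1::2], 1e-4 * lam[1] ** 2, atol=1e-12)


class TestAdjointGradients:
    """The reverse-mode moment gradients must agree with finite differences."""

    @pytest.mark.parametrize("kind", ["riclpm", "altsr"])
    def test_adjoint_matches_finite_differences(self, kind, schedule):
        idx = build_riclpm(4) if kind == "riclpm" else build_altsr(
            4, type(schedule)(labels=("dep", "cm"),
                              ages=((10.0, 12.0, 14.0, 16.0), (9.0, 11.5, 14.0, 17.0))))
        rng = np.random.default_rng(23)
        x = rng.normal(scale=0.4, size=idx.n_free)
        Gbar = rng.normal(size=(8, 8))
        Gbar = (Gbar + Gbar.T) / 2
        mubar = rng.normal(size=8)
        mu, Sigma, backward = idx.moments_and_adjoint(x)
        grad = backward(Gbar, mubar)

        def scalar(xv):
            m, S = idx.moments(xv)
            return np.sum(Gbar * S) + mubar @ m

        fd = np.empty_like(x)
        for j in range(x.size):
            h = 1e-6 * max(1, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd[j] = (scalar(xp) - scalar(xm)) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=2e-5, atol=1e-7)
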