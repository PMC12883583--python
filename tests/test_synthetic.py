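import numpy as np
import pytest

from riclpm.model import InvalidParameterError, implied_moments
from riclpm.panel import RawPanel, read_panel
from riclpm.reference import REFERENCE_MISSING_CM, REFERENCE_MISSING_DEP
from riclpm.synthetic import (
    GeneratingTruth,
    LinkSpec,
    MissingSpec,
    alspac_like_truth,
    emit_fixture,
    simulate_panel,
)


class TestDefaultTruth:
    def test_six_waves_and_five_lag_matrices(self, truth):
        assert truth.params.T == 6
        assert truth.params.B.shape == (5, 2, 2)

    def test_intercept_correlation_matches_cohort_value(self, truth):
        psi = truth.params.psi
        r = psi[0, 1] / np.sqrt(psi[0, 0] * psi[1, 1])
        assert r == pytest.approx(0.11, abs=1e-12)

    def test_implied_covariance_symmetric_positive_definite(self, truth):
        _, Sigma = implied_moments(truth.params)
        np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-14)
        assert np.linalg.eigvalsh(Sigma).min() > 0

    def test_standardized_coefficients_match_published_magnitudes(self, truth):
        # AR and CL magnitudes on the standardized scale equal the published
        # table by construction (constant within variances over waves)
        std = truth.standardized_B()
        assert std[0, 1, 1] == pytest.approx(0.84, abs=1e-10)   # adiposity AR, lag 1
        assert std[4, 1, 1] == pytest.approx(0.54, abs=1e-10)
        assert std[2, 0, 1] == pytest.approx(0.13, abs=1e-10)   # cm -> dep, lag 3
        assert std[2, 1, 0] == pytest.approx(0.05, abs=1e-10)   # dep -> cm, lag 3


class TestSimulate:
    def test_no_missingness_gives_complete_rows(self, truth):
        panel = simulate_panel(truth, n=40, seed=0)
        assert panel.n == 40
        assert not np.any(np.isnan(panel.values))
        # questionnaire totals are integers within instrument range
        dep = panel.construct_values(0)
        assert np.all(dep == np.round(dep))
        assert dep.min() >= 0 and dep.max() <= 26
        assert np.all(panel.construct_values(1) > 0)

    def test_identical_seeds_reproduce_identical_bytes(self, truth, tmp_path):
        spec = MissingSpec.alspac_like()
        a = simulate_panel(truth, n=60, missing=spec, seed=42)
        b = simulate_panel(truth, n=60, missing=spec, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        emit_fixture(a, tmp_path / "a.csv")
        emit_fixture(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_mcar_rate_converges_to_target(self, truth):
        rates = ((0.0, 0.0, 0.30, 0.0, 0.0, 0.0), (0.0,) * 6)
        spec = MissingSpec(rates=rates, mechanism="mcar")
        panel = simulate_panel(truth, n=50_000, missing=spec, seed=7)
        frac = np.isnan(panel.construct_values(0)[:, 2]).mean()
        assert frac == pytest.approx(0.30, abs=0.01)
        assert not np.any(np.isnan(panel.construct_values(1)))

    def test_mar_realized_rates_match_profile(self, truth):
        spec = MissingSpec.alspac_like(mechanism="mar")
        panel = simulate_panel(truth, n=30_000, missing=spec, seed=3)
        for c, targets in enumerate([REFERENCE_MISSING_DEP, REFERENCE_MISSING_CM]):
            realized = np.isnan(panel.construct_values(c)).mean(axis=0)
            np.testing.assert_allclose(realized, targets, atol=0.02)

    def test_mar_missingness_depends_on_previous_score(self, truth):
        # higher previous-wave scores should be more likely missing next wave
        spec = MissingSpec.alspac_like(mechanism="mar")
        panel = simulate_panel(truth, n=40_000, missing=spec, seed=9)
        dep = panel.construct_values(0)
        prev = dep[:, 3]
        has_prev = ~np.isnan(prev)
        miss_next = np.isnan(dep[:, 4])
        hi = prev[has_prev] > np.nanmedian(prev)
        assert miss_next[has_prev][hi].mean() > miss_next[has_prev][~hi].mean() + 0.02

    def test_latent_regression_recovers_cross_lag(self, truth):
        # OLS of wave-(t+1) within-components on wave-t within-components
        # is an independent oracle for the lag-1 recursion
        _, lat = simulate_panel(truth, n=50_000, seed=13, return_latent=True)
        w = lat["within"]
        for t in range(5):
            X = w[:, t, :]
            for i in range(2):
                coef, *_ = np.linalg.lstsq(X, w[:, t + 1, i], rcond=None)
                np.testing.assert_allclose(coef, truth.params.B[t, i, :], atol=0.02)

    def test_zero_coupling_zero_intercepts_gives_independent_waves(self, truth):
        p = truth.params
        params = type(p)(psi=np.zeros((2, 2)), theta1=p.theta1,
                         B=np.zeros_like(p.B), theta=p.theta, mu=p.mu)
        t2 = GeneratingTruth(params=params, links=truth.links).model_scale()
        panel = simulate_panel(t2, n=20_000, seed=21)
        y = panel.values
        for t in range(5):
            for c in range(2):
                r = np.corrcoef(y[:, 2 * t + c], y[:, 2 * (t + 1) + c])[0, 1]
                assert abs(r) < 0.025

    def test_intercept_variance_raises_between_wave_covariances(self, truth):
        p = truth.params
        tau = 0.01
        base = type(p)(psi=np.zeros((2, 2)), theta1=p.theta1, B=p.B,
                       theta=p.theta, mu=p.mu)
        bumped = type(p)(psi=tau * np.eye(2), theta1=p.theta1, B=p.B,
                         theta=p.theta, mu=p.mu)
        pa = simulate_panel(GeneratingTruth(base, truth.links).model_scale(), n=60_000, seed=2)
        pb = simulate_panel(GeneratingTruth(bumped, truth.links).model_scale(), n=60_000, seed=2)
        ca = np.cov(pa.values.T)
        cb = np.cov(pb.values.T)
        for c in range(2):
            for t in range(6):
                for s in range(t):
                    shift = cb[2 * t + c, 2 * s + c] - ca[2 * t + c, 2 * s + c]
                    assert shift == pytest.approx(tau, abs=0.003)

    def test_invalid_inputs_raise(self, truth):
        bad_psi = truth.params.psi.copy()
        bad_psi[0, 1] = bad_psi[1, 0] = 1.0  # correlation > 1: not PSD
        p = truth.params
        bad = GeneratingTruth(
            params=type(p)(psi=bad_psi, theta1=p.theta1, B=p.B, theta=p.theta, mu=p.mu),
            links=truth.links,
        )
        with pytest.raises(InvalidParameterError):
            simulate_panel(bad, n=10, seed=0)
        with pytest.raises(ValueError):
            simulate_panel(truth, n=0, seed=0)

    def test_fixture_roundtrip_through_reader(self, truth, tmp_path):
        panel = simulate_panel(truth, n=25, missing=MissingSpec.alspac_like(), seed=5)
        emit_fixture(panel, tmp_path / "fix.csv")
        again = read_panel(tmp_path / "fix.csv")
        np.testing.assert_array_equal(panel.values, again.values)
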