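"""AR(2) process: stationarity checks, simulation, conditional-ML fitting,
and the Poisson-log-normal latent rate model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.tsa.arima_process import arma_acovf

from capdyn import (
    AR2Model,
    AR2Spec,
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    MissingValuesError,
    PoissonRateModel,
    check_stationarity,
    simulate_ar2,
    stationary_variance,
)

PAPER_COMBOS = [(p1, p2) for p2 in (-0.8, -0.5, -0.2) for p1 in (-1, -0.5, 0, 0.5, 1)]


class TestStationarity:
    @pytest.mark.parametrize(
        "phi1,phi2,stat,pseudo",
        [
            (0.5, -0.2, True, True),   # 0.25 - 0.8 <= 0
            (1.0, 0.5, False, False),  # phi1 + phi2 > 1
            (0.0, 0.0, True, True),    # boundary: 0 <= 0
            (-1.0, -0.2, True, False),  # 1 - 0.8 > 0: real roots
            (0.0, 1.2, False, False),
        ],
    )
    def test_examples(self, phi1, phi2, stat, pseudo):
        assert check_stationarity(phi1, phi2) == (stat, pseudo)

    @given(
        phi1=st.floats(min_value=-2, max_value=2),
        phi2=st.floats(min_value=-2, max_value=2),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_root_criterion(self, phi1, phi2):
        """The triangle condition agrees with the characteristic roots of
        z^2 - phi1 z - phi2 lying strictly inside the unit circle."""
        roots = np.roots([1.0, -phi1, -phi2])
        by_roots = bool(np.all(np.abs(roots) < 1 - 1e-12)) or bool(
            np.all(np.abs(roots) < 1 + 1e-12) and np.all(np.abs(roots) < 1)
        )
        near_edge = abs(max(np.abs(np.roots([1.0, -phi1, -phi2]))) - 1) < 1e-9
        if not near_edge:
            assert check_stationarity(phi1, phi2)[0] == by_roots


class TestStationaryVariance:
    @pytest.mark.parametrize(
        "phi1,phi2,s2,expected",
        [
            (0, 0, 1.0, 1.0),
            (0, -0.5, 0.08, 0.10667),
            (1, -0.8, 0.64, 2.5714),
        ],
    )
    def test_closed_form(self, phi1, phi2, s2, expected):
        assert stationary_variance(phi1, phi2, s2) == pytest.approx(
            expected, abs=5e-5
        )

    @pytest.mark.parametrize("phi1,phi2", PAPER_COMBOS)
    def test_matches_acovf_oracle(self, phi1, phi2):
        """Closed form equals the lag-0 autocovariance computed by the
        independent ARMA autocovariance routine."""
        gamma0 = arma_acovf([1, -phi1, -phi2], [1], nobs=1, sigma2=0.08)[0]
        assert stationary_variance(phi1, phi2, 0.08) == pytest.approx(
            gamma0, rel=1e-10
        )

    def test_nonstationary_rejected(self):
        with pytest.raises(DomainError):
            stationary_variance(1.0, 0.5, 1.0)


class TestSimulate:
    def test_zero_noise_constant_at_mean(self):
        spec = AR2Spec(0.5, -0.2, 0.0, offset_log_eta=2.1, T=10)
        x = simulate_ar2(spec, 0)
        np.testing.assert_allclose(x, 2.1 / (1 - 0.5 + 0.2))

    def test_white_noise_acf(self):
        spec = AR2Spec(0.0, 0.0, 1.0, T=100_000)
        x = simulate_ar2(spec, 1)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(spec.T)

    def test_lag1_autocorrelation_yule_walker(self):
        """Sample lag-1 autocorrelation matches phi1/(1-phi2)."""
        spec = AR2Spec(0.5, -0.2, 1.0, T=100_000)
        x = simulate_ar2(spec, 2)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.5 / 1.2, abs=0.01)

    def test_variance_matches_closed_form(self):
        spec = AR2Spec(0.5, -0.5, 0.3, T=200_000)
        x = simulate_ar2(spec, 3)
        assert x.var() == pytest.approx(spec.stationary_var, rel=0.02)

    def test_nonstationary_rejected(self):
        with pytest.raises(DomainError):
            simulate_ar2(AR2Spec(1.0, 0.5, 1.0), 0)


class TestAR2Fit:
    @pytest.mark.parametrize("phi1,phi2", [(0.5, -0.2), (-1.0, -0.8), (1.0, -0.5)])
    def test_noiseless_exact_recovery(self, phi1, phi2):
        """A deterministic AR(2) recursion identifies (phi1, phi2) exactly."""
        x = np.empty(30)
        x[0], x[1] = 1.3, -0.7
        for t in range(2, 30):
            x[t] = 0.4 + phi1 * x[t - 1] + phi2 * x[t - 2]
        res = AR2Model(x).fit()
        assert res.phi1 == pytest.approx(phi1, abs=1e-8)
        assert res.phi2 == pytest.approx(phi2, abs=1e-8)
        assert res.intercept == pytest.approx(0.4, abs=1e-7)

    def test_offset_invariance(self):
        """Adding a constant to the series leaves (phi1, phi2) untouched."""
        x = simulate_ar2(AR2Spec(0.5, -0.2, 0.08, T=20), 5)
        a = AR2Model(x).fit()
        b = AR2Model(x + 7.0).fit()
        assert a.phi1 == pytest.approx(b.phi1, abs=1e-10)
        assert a.phi2 == pytest.approx(b.phi2, abs=1e-10)
        assert b.intercept != pytest.approx(a.intercept, abs=1e-3)

    @pytest.mark.parametrize("phi1,phi2", [(0.5, -0.2), (-1.0, -0.8), (1.0, -0.8)])
    def test_short_series_shrinkage(self, phi1, phi2):
        """At T=20 the direct-density-dependence coefficient is biased toward
        zero on average; the delayed coefficient shrinks too once it is
        strong (the small-sample bias grows with the coefficient
        magnitudes)."""
        p1h, p2h = [], []
        for seed in range(200):
            x = simulate_ar2(AR2Spec(phi1, phi2, 0.08, T=20), seed)
            res = AR2Model(x).fit()
            p1h.append(res.phi1)
            p2h.append(res.phi2)
        assert abs(np.mean(p1h)) < abs(phi1)
        if abs(phi2) >= 0.8:
            assert np.mean(p2h) > phi2

    @pytest.mark.parametrize("phi1,phi2", PAPER_COMBOS)
    def test_round_trip_long_series(self, phi1, phi2):
        x = simulate_ar2(AR2Spec(phi1, phi2, 0.08, T=2000), 17)
        res = AR2Model(x).fit()
        assert res.phi1 == pytest.approx(phi1, abs=0.05)
        assert res.phi2 == pytest.approx(phi2, abs=0.05)

    def test_exact_method_agrees_at_large_t(self):
        x = simulate_ar2(AR2Spec(0.5, -0.5, 0.2, T=3000), 23)
        cml = AR2Model(x).fit()
        exact = AR2Model(x).fit(method="exact")
        assert cml.phi1 == pytest.approx(exact.phi1, abs=0.01)
        assert cml.phi2 == pytest.approx(exact.phi2, abs=0.01)

    def test_interval_ordering_and_covers(self):
        x = simulate_ar2(AR2Spec(0.5, -0.2, 0.08, T=20), 31)
        res = AR2Model(x).fit()
        lo1, hi1 = res.ci_phi1
        assert lo1 < res.phi1 < hi1
        assert res.covers(res.phi1, res.phi2) == (True, True)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            AR2Model([1.0, 2.0, 1.5, 0.5])

    def test_missing_values(self):
        with pytest.raises(MissingValuesError, match="split"):
            AR2Model([1.0, np.nan, 1.5, 0.5, 0.3, 0.2])

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateDataError):
            AR2Model(np.ones(10)).fit()


class TestPoissonRate:
    def test_constant_counts(self):
        """No overdispersion: the latent sd collapses and every log rate
        equals ln(c)."""
        res = PoissonRateModel(np.full(12, 7)).fit()
        assert res.kappa_e > 1e2
        np.testing.assert_allclose(res.lambda_hat, np.log(7), atol=0.02)

    def test_large_counts_track_log_counts(self):
        """When counts are large the Poisson noise vanishes and the
        posterior-mean log rates sit on ln(y_t)."""
        rng = np.random.default_rng(4)
        lam = np.exp(rng.normal(8.0, 0.5, 15))
        y = rng.poisson(lam)
        res = PoissonRateModel(y).fit()
        np.testing.assert_allclose(res.lambda_hat, np.log(y), atol=0.02)

    def test_monotone_in_counts(self):
        res = PoissonRateModel([2, 6, 20, 70, 200]).fit()
        assert (np.diff(res.lambda_hat) > 0).all()

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateDataError):
            PoissonRateModel(np.zeros(8, dtype=int))

    def test_zero_counts_allowed(self):
        res = PoissonRateModel([0, 3, 5, 0, 2, 8, 1]).fit()
        assert np.isfinite(res.lambda_hat).all()

    def test_marginal_likelihood_against_quadrature_oracle(self):
        """The adaptive-GH marginal likelihood matches brute-force numerical
        integration at fixed (beta0, sigma2)."""
        from scipy.integrate import quad
        from scipy.stats import norm, poisson

        y = np.array([3, 0, 7, 12, 5])
        beta0, sigma2 = 1.4, 0.6
        model = PoissonRateModel(y)
        ll = model.loglike(beta0, sigma2)
        brute = 0.0
        for yt in y:
            val, _ = quad(
                lambda e, yt=yt: poisson.pmf(yt, np.exp(beta0 + e))
                * norm.pdf(e, 0, np.sqrt(sigma2)),
                -8, 8, limit=200,
            )
            brute += np.log(val)
        assert ll == pytest.approx(brute, abs=1e-8)
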