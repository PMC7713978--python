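"""Capture-model tests: category probabilities, design building, conditional
multinomial fitting and its Poisson-transformation equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from capdyn import (
    CaptureModel,
    ConvergenceError,
    DomainError,
    EmptyCategoryError,
    InputError,
    UnsupportedOperationError,
    build_design,
    category_probabilities,
    expand_to_poisson,
)
from conftest import make_records

probs = st.floats(min_value=0.01, max_value=0.99)


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.5, 0.5, (0.25, 0.25, 0.25, 0.25)),
            (0.55, 0.75, (0.1125, 0.1375, 0.3375, 0.4125)),
        ],
    )
    def test_values(self, p1, p2, expected):
        cp = category_probabilities(p1, p2)
        assert (cp.c0, cp.c1, cp.c2, cp.c3) == pytest.approx(expected, abs=1e-12)

    def test_conditional_triple(self):
        cp = category_probabilities(0.55, 0.75)
        assert cp.c_tilde3 == pytest.approx(0.4125 / 0.8875, abs=1e-9)
        assert cp.c_tilde1 + cp.c_tilde2 + cp.c_tilde3 == pytest.approx(1.0)

    @pytest.mark.parametrize("p1,p2", [(0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_domain(self, p1, p2):
        with pytest.raises(DomainError):
            category_probabilities(p1, p2)

    @given(p1=probs, p2=probs)
    @settings(max_examples=50, deadline=None)
    def test_normalization(self, p1, p2):
        cp = category_probabilities(p1, p2)
        assert cp.c0 + cp.c1 + cp.c2 + cp.c3 == pytest.approx(1.0, abs=1e-12)
        assert cp.c_tilde1 + cp.c_tilde2 + cp.c_tilde3 == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= c <= 1 for c in (cp.c0, cp.c1, cp.c2, cp.c3))


class TestBuildDesign:
    @pytest.mark.parametrize(
        "hist,row", [((1, 1), (0, 0, 1)), ((1, 0), (1, 0, 0)), ((0, 1), (0, 1, 0))]
    )
    def test_category_mapping(self, hist, row):
        rec = pd.DataFrame(
            {"w1": [hist[0]], "w2": [hist[1]], "weight": [1.0]}
        )
        d = build_design(rec, ["weight"])
        assert tuple(d.y[0]) == row

    def test_shape_contract(self):
        d = build_design(make_records((1, 1, 1)), ["weight"])
        assert d.y.shape == (3, 3) and d.z.shape == (3, 1)
        assert d.columns == ["weight"]

    def test_never_captured_rejected(self):
        rec = pd.DataFrame({"w1": [0], "w2": [0], "weight": [1.0]})
        with pytest.raises(InputError, match=r"\(0,0\)"):
            build_design(rec, ["weight"])

    def test_missing_covariate(self):
        rec = pd.DataFrame({"w1": [1], "w2": [1], "weight": [1.0]})
        with pytest.raises(InputError, match="length"):
            build_design(rec, ["length"])

    def test_categorical_expansion_alphabetical_baseline(self):
        rec = make_records((2, 2, 2))
        rec["sex"] = ["m", "f", "m", "f", "m", "f"]
        d = build_design(rec, ["weight", "sex"])
        # 'f' is the alphabetical baseline, so only the 'm' indicator appears
        assert d.columns == ["weight", "sex[m]"]
        assert set(d.z[:, 1]) == {0.0, 1.0}


class TestPoissonExpansion:
    def test_three_rows_per_individual(self):
        d = build_design(make_records((1, 0, 1)), ["weight"])
        table = expand_to_poisson(d)
        assert len(table) == 6
        assert (table.groupby("individual")["y"].sum() == 1).all()

    def test_equivalence_with_direct_ml(self):
        """Augmented Poisson GLM and direct conditional multinomial ML agree
        to 1e-6 in the coefficient differences on a random 50-row design."""
        rng = np.random.default_rng(7)
        z = rng.normal(0.8, 0.5, 50)
        p1, p2 = expit(0.3 * z), expit(1.0 * z)
        w1 = rng.random(50) < p1
        w2 = rng.random(50) < p2
        keep = w1 | w2
        rec = pd.DataFrame(
            {"w1": w1[keep].astype(int), "w2": w2[keep].astype(int),
             "weight": z[keep]}
        )
        model = CaptureModel.from_records(rec, ["weight"])
        direct = model.fit()
        augmented = model.fit_poisson_augmented()
        np.testing.assert_allclose(direct.delta1, augmented.delta1, atol=1e-6)
        np.testing.assert_allclose(direct.delta2, augmented.delta2, atol=1e-6)

    def test_direct_fit_matches_brute_force(self):
        """The Newton fit maximizes the same conditional multinomial
        likelihood as a generic optimizer started elsewhere."""
        rec = make_records((15, 25, 40))
        model = CaptureModel.from_records(rec, ["weight"], add_intercept=True)
        res = model.fit()
        brute = minimize(
            lambda t: -model.loglike(t), np.full(4, 0.3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert -brute.fun <= res.llf + 1e-7
        np.testing.assert_allclose(res.params, brute.x, atol=1e-4)


class TestCaptureFit:
    def test_intercept_only_closed_form(self):
        """Intercept-only conditional ML gives the classical two-sample
        estimates p1 = n3/(n2+n3), p2 = n3/(n1+n3)."""
        rec = make_records((20, 30, 50))
        res = CaptureModel.from_records(rec, [], add_intercept=True).fit()
        assert res.p1_hat[0] == pytest.approx(50 / 80, abs=1e-8)
        assert res.p2_hat[0] == pytest.approx(50 / 70, abs=1e-8)
        assert np.ptp(res.p1_hat) < 1e-12  # constant across individuals

    def test_parameter_recovery_large_n(self):
        """With a single standardized covariate, the fit recovers the true
        logit coefficients within 3 Monte-Carlo standard errors at n=5000."""
        rng = np.random.default_rng(11)
        d1, d2 = logit(0.55), logit(0.75)
        z = rng.lognormal(0, 0.4, 8000)
        z = z / z.std(ddof=1)
        w1 = rng.random(z.size) < expit(d1 * z)
        w2 = rng.random(z.size) < expit(d2 * z)
        keep = w1 | w2
        rec = pd.DataFrame(
            {"w1": w1[keep].astype(int), "w2": w2[keep].astype(int),
             "weight": z[keep]}
        )
        res = CaptureModel.from_records(rec, ["weight"]).fit()
        se = res.bse_delta
        assert abs(res.delta1[0] - d1) < 3 * se[0]
        assert abs(res.delta2[0] - d2) < 3 * se[1]

    def test_separation_raises(self):
        """A covariate that perfectly separates categories is not estimable."""
        rec = make_records((10, 10, 10), weights=[1.0] * 10 + [2.0] * 10 + [9.0] * 10)
        with pytest.raises(ConvergenceError):
            CaptureModel.from_records(rec, ["weight"], add_intercept=True).fit(
                maxiter=500
            )

    def test_empty_category_named(self):
        rec = make_records((10, 10, 0))
        with pytest.raises(EmptyCategoryError) as err:
            CaptureModel.from_records(rec, ["weight"])
        assert err.value.category == 3

    def test_never_capture_probability_identity(self, heterogeneous_records):
        rec, _ = heterogeneous_records
        res = CaptureModel.from_records(rec, ["weight"]).fit()
        np.testing.assert_allclose(
            res.c0_hat, (1 - res.p1_hat) * (1 - res.p2_hat), atol=1e-14
        )
        assert ((res.c0_hat > 0) & (res.c0_hat < 1)).all()

    def test_reference_category_invariance(self, heterogeneous_records):
        """delta1, delta2 do not depend on which category is the reference."""
        rec, _ = heterogeneous_records
        fits = [
            CaptureModel.from_records(rec, ["weight"], reference=k).fit()
            for k in (1, 2, 3)
        ]
        for other in fits[1:]:
            np.testing.assert_allclose(fits[0].delta1, other.delta1, atol=1e-8)
            np.testing.assert_allclose(fits[0].delta2, other.delta2, atol=1e-8)

    def test_bayes_mode_close_to_ml(self, heterogeneous_records):
        rec, _ = heterogeneous_records
        model = CaptureModel.from_records(rec, ["weight"])
        ml = model.fit()
        bayes = model.fit(bayes=True)
        np.testing.assert_allclose(ml.delta1, bayes.delta1, atol=5e-3)
        with pytest.raises(UnsupportedOperationError):
            bayes.aic


class TestInformationCriteria:
    def test_formula(self, petersen_records):
        res = CaptureModel.from_records(petersen_records, [], add_intercept=True).fit()
        res.llf = -50.0
        res.params = np.zeros(2)  # q = 2 free coefficients, n = 100
        assert res.aic == pytest.approx(104.0)
        assert res.bic == pytest.approx(109.2103, abs=1e-4)

    def test_monotone_in_loglike(self, heterogeneous_records):
        rec, _ = heterogeneous_records
        model = CaptureModel.from_records(rec, ["weight"])
        a = model.fit()
        b = model.fit()
        b.llf = a.llf + 5.0
        assert b.aic < a.aic

    def test_informative_covariate_lowers_aic(self, heterogeneous_records):
        """Weight truly drives capture, so adding it must beat the
        intercept-only model on AIC."""
        rec, _ = heterogeneous_records
        plain = CaptureModel.from_records(rec, [], add_intercept=True).fit()
        with_w = CaptureModel.from_records(
            rec, ["weight"], add_intercept=True
        ).fit()
        assert with_w.aic < plain.aic


def test_summary_and_report(heterogeneous_records):
    rec, _ = heterogeneous_records
    res = CaptureModel.from_records(rec, ["weight"]).fit()
    text = res.summary()
    assert "delta1[weight]" in text and "AIC" in text
    report = res.to_dict()
    assert set(report) >= {"delta1", "delta2", "aic", "bic", "loglike"}
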