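"""Weighted Cox machinery: Barlow weights, estimation, risks, associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from conftest import weibull_ph_data
from omicox.survcox import (
    BarlowWeights,
    barlow_weights,
    fit_cox,
    hazard_ratio_per_sd,
    predict_absolute_risk,
)
from omicox.synthdata import CaseCohortSample, SurvivalOutcome


def _toy_sample(alpha, in_sub, is_case):
    n = len(in_sub)
    return CaseCohortSample(
        data=pd.DataFrame({"x": np.zeros(n)}),
        outcome=SurvivalOutcome(np.arange(1, n + 1, dtype=float), is_case),
        in_subcohort=np.asarray(in_sub, bool),
        is_case=np.asarray(is_case, bool),
        alpha=alpha,
    )


class TestBarlowWeights:
    def test_full_cohort_gives_unit_weights(self):
        s = _toy_sample(1.0, [1, 1, 1], np.array([0, 1, 0]))
        w = barlow_weights(s)
        assert np.all(w.pre_event == 1.0) and np.all(w.at_event == 1.0)

    def test_subcohort_noncase_gets_inverse_alpha(self):
        s = _toy_sample(0.5, [1, 1], np.array([0, 1]))
        w = barlow_weights(s)
        assert w.pre_event[0] == 2.0  # non-case: 1/alpha throughout
        assert w.pre_event[1] == 2.0 and w.at_event[1] == 1.0  # subcohort case

    def test_nonsubcohort_case_enters_only_at_failure(self):
        s = _toy_sample(0.25, [1, 0], np.array([0, 1]))
        w = barlow_weights(s)
        assert w.pre_event[1] == 0.0 and w.at_event[1] == 1.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            _toy_sample(0.0, [1], np.array([1]))


class TestFitCox:
    def test_single_binary_covariate_matches_scalar_score_equation(self):
        # independent oracle: 1-d root of the Breslow score equation
        rng = np.random.default_rng(3)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.7 * x))  # continuous, ties a.s. absent
        assert len(np.unique(t)) == n
        e = np.ones(n, dtype=int)
        out = SurvivalOutcome(t, e)

        order = np.argsort(-t)
        xs = x[order]

        def score(beta):
            r = np.exp(beta * xs)
            c0 = np.cumsum(r)
            c1 = np.cumsum(r * xs)
            return np.sum(xs - c1 / c0)

        beta_oracle = brentq(score, -5, 5, xtol=1e-12)
        fit = fit_cox(x[:, None], out)
        assert abs(fit.beta[0] - beta_oracle) < 1e-8

    def test_matches_reference_implementation_unit_weights(self, small_cox_fixture):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        X, out = small_cox_fixture
        fit = fit_cox(X, out)
        y = np.array(
            list(zip(out.event.astype(bool), out.time)),
            dtype=[("e", bool), ("t", float)],
        )
        ref = CoxPHSurvivalAnalysis(alpha=0.0, ties="breslow", tol=1e-12,
                                    n_iter=200).fit(X.to_numpy(), y)
        np.testing.assert_allclose(fit.beta, ref.coef_, atol=1e-6)

    def test_duplicated_column_raises_collinearity_error(self, small_cox_fixture):
        X, out = small_cox_fixture
        X2 = X.copy()
        X2["dup"] = X2["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(X2, out)

    def test_alpha_one_case_cohort_equals_unweighted_fit(self, small_cox_fixture):
        X, out = small_cox_fixture
        n = len(X)
        w = BarlowWeights(np.ones(n), np.ones(n))
        fit_w = fit_cox(X, out, w)
        fit_u = fit_cox(X, out)
        np.testing.assert_array_equal(fit_w.beta, fit_u.beta)
        np.testing.assert_array_equal(fit_w.robust_se, fit_u.robust_se)

    def test_requires_events(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        out = SurvivalOutcome(np.arange(1.0, 21.0), np.zeros(20, int))
        with pytest.raises(ValueError, match="event"):
            fit_cox(X, out)


class TestPredictAbsoluteRisk:
    def test_average_subject_risk_is_baseline_identity(self, small_cox_fixture):
        X, out = small_cox_fixture
        fit = fit_cox(X, out)
        h = float(out.time.max())
        xbar = pd.DataFrame([fit.center], columns=X.columns)
        risk = predict_absolute_risk(fit, xbar, h)
        assert risk[0] == pytest.approx(1.0 - np.exp(-fit.cumhaz_at(h)))

    def test_strongly_protective_predictor_drives_risk_to_zero(self, small_cox_fixture):
        X, out = small_cox_fixture
        fit = fit_cox(X, out)
        extreme = X.iloc[[0]] - 1e3 * np.sign(fit.beta)
        risk = predict_absolute_risk(fit, extreme, float(out.time.max()))
        assert risk[0] < 1e-10

    def test_horizon_beyond_followup_rejected(self, small_cox_fixture):
        X, out = small_cox_fixture
        fit = fit_cox(X, out)
        with pytest.raises(ValueError, match="horizon"):
            predict_absolute_risk(fit, X, out.time.max() + 1.0)

    def test_mean_predicted_risk_matches_empirical_incidence(self):
        X, out = weibull_ph_data(7, 5000, [0.5, -0.4], censor_scale=None,
                                 target_events=0.2)
        fit = fit_cox(X, out)
        risk = predict_absolute_risk(fit, X, 10.0)
        assert abs(risk.mean() - out.event.mean()) < 0.01


class TestHazardRatioPerSd:
    def _frame(self, seed=5, n=1500):
        X, out = weibull_ph_data(seed, n, [0.4, 0.3, -0.2, 0.25, 0.2, -0.15,
                                           0.2, -0.1, 0.5],
                                 censor_scale=40.0, target_events=0.25)
        from omicox.synthdata import SCORE2_VARIABLES

        df = pd.DataFrame(X[:, :8], columns=SCORE2_VARIABLES)
        df["marker"] = X[:, 8]
        df["sex"] = np.where(np.random.default_rng(seed).random(n) < 0.5, "M", "F")
        return df, out

    def test_sd_standardization_is_scale_invariant(self):
        df, out = self._frame()
        w = BarlowWeights.unit(len(df))
        a1 = hazard_ratio_per_sd("marker", df, out, w, sex="M")
        df2 = df.copy()
        df2["marker"] = 10.0 * df2["marker"]
        a2 = hazard_ratio_per_sd("marker", df2, out, w, sex="M")
        assert a1.hazard_ratio == pytest.approx(a2.hazard_ratio, rel=1e-10)

    def test_planted_signal_detected(self):
        df, out = self._frame()
        w = BarlowWeights.unit(len(df))
        a = hazard_ratio_per_sd("marker", df, out, w, sex="M")
        assert a.hazard_ratio > 1.0 and a.p_value < 1e-3
        assert a.ci_low <= a.hazard_ratio <= a.ci_high

    def test_zero_variance_feature_rejected(self):
        df, out = self._frame()
        df["flat"] = 1.0
        w = BarlowWeights.unit(len(df))
        with pytest.raises(ValueError, match="variance"):
            hazard_ratio_per_sd("flat", df, out, w, sex="M")
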