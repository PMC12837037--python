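"""Discrimination, reclassification, calibration and correlation metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_c, weibull_ph_data
from omicox.evalmetrics import (
    calibration_deciles,
    categorical_nri,
    compare_c,
    continuous_nri,
    harrell_c,
    idi,
    incremental_c,
    spearman_matrix,
)
from omicox.synthdata import SurvivalOutcome


def _random_censored_fixture(seed, n):
    rng = np.random.default_rng(seed)
    t = np.round(rng.exponential(1.0, n), 1)  # rounded -> ties in time
    e = (rng.random(n) < 0.6).astype(int)
    risk = np.round(rng.random(n), 1)         # ties in score
    return risk, SurvivalOutcome(t, e)


class TestHarrellC:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_enumeration(self, seed):
        risk, out = _random_censored_fixture(seed, 150)
        c, _ = harrell_c(risk, out)
        assert c == pytest.approx(brute_force_c(risk, out.time, out.event),
                                  abs=1e-12)

    def test_perfect_ranking_gives_one(self):
        t = np.arange(1.0, 21.0)
        out = SurvivalOutcome(t, np.ones(20, int))
        c, _ = harrell_c(-t, out)
        assert c == 1.0

    def test_constant_risk_gives_half(self):
        risk, out = _random_censored_fixture(3, 100)
        c, _ = harrell_c(np.zeros(100), out)
        assert c == 0.5

    def test_no_comparable_pairs_rejected(self):
        out = SurvivalOutcome(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([0.1, 0.2]), out)

    def test_ci_brackets_estimate(self):
        risk, out = _random_censored_fixture(4, 300)
        c, (lo, hi) = harrell_c(risk, out)
        assert lo <= c <= hi and hi - lo < 0.5


class TestCompareC:
    def test_identical_models_give_zero_delta_p_one(self):
        risk, out = _random_censored_fixture(5, 200)
        res = compare_c(risk, risk, out)
        assert res.delta_c == 0.0 and res.p_value == 1.0

    def test_mismatched_lengths_rejected(self):
        risk, out = _random_censored_fixture(6, 100)
        with pytest.raises(ValueError, match="same subjects"):
            compare_c(risk, risk[:-1], out)

    def test_delta_equals_c_difference(self):
        r1, out = _random_censored_fixture(7, 200)
        r2 = np.random.default_rng(8).random(200)
        res = compare_c(r1, r2, out)
        c1, _ = harrell_c(r1, out)
        c2, _ = harrell_c(r2, out)
        assert res.delta_c == pytest.approx(c2 - c1, abs=1e-12)


def _uncensored_toy():
    # events before the horizon, non-events followed beyond it
    t = np.array([1.0, 2.0, 11.0, 12.0, 13.0, 14.0, 15.0, 8.0])
    e = np.array([1, 1, 0, 0, 0, 0, 0, 1])
    out = SurvivalOutcome(t, e)
    p_ref = np.full(8, 0.10)
    p_new = np.array([0.20, 0.20, 0.10, 0.10, 0.10, 0.10, 0.20, 0.10])
    return p_ref, p_new, out


class TestReclassification:
    def test_categorical_nri_matches_hand_counts(self):
        p_ref, p_new, out = _uncensored_toy()
        res = categorical_nri(p_ref, p_new, out, with_ci=False)
        # events: 2 of 3 up; non-events: 1 of 5 up
        assert res.nri_events == pytest.approx(2 / 3)
        assert res.nri_nonevents == pytest.approx(-1 / 5)
        assert res.nri_total == pytest.approx(2 / 3 - 1 / 5)

    def test_identity_and_antisymmetry(self):
        p_ref, p_new, out = _uncensored_toy()
        same = categorical_nri(p_ref, p_ref, out, with_ci=False)
        assert same.nri_total == 0.0
        fwd = categorical_nri(p_ref, p_new, out, with_ci=False)
        rev = categorical_nri(p_new, p_ref, out, with_ci=False)
        assert fwd.nri_total == pytest.approx(-rev.nri_total, abs=1e-15)

    def test_continuous_nri_identity_antisymmetry_and_hand_count(self):
        p_ref, p_new, out = _uncensored_toy()
        assert continuous_nri(p_ref, p_ref, out, with_ci=False).nri_total == 0.0
        fwd = continuous_nri(p_ref, p_new, out, with_ci=False)
        rev = continuous_nri(p_new, p_ref, out, with_ci=False)
        assert fwd.nri_total == pytest.approx(-rev.nri_total, abs=1e-15)
        assert fwd.nri_total == pytest.approx(2 / 3 - 1 / 5)

    def test_idi_matches_discrimination_slope_difference(self):
        p_ref, p_new, out = _uncensored_toy()
        val, _ = idi(p_ref, p_new, out, with_ci=False)
        d = p_new - p_ref
        expected = d[out.event == 1].mean() - d[out.event == 0].mean()
        assert val == pytest.approx(expected, abs=1e-15)
        rev, _ = idi(p_new, p_ref, out, with_ci=False)
        assert rev == pytest.approx(-val, abs=1e-15)

    def test_invalid_cuts_rejected(self):
        p_ref, p_new, out = _uncensored_toy()
        with pytest.raises(ValueError, match="cuts"):
            categorical_nri(p_ref, p_new, out, cuts=(0.3, 0.15), with_ci=False)

    def test_invalid_probabilities_rejected(self):
        p_ref, p_new, out = _uncensored_toy()
        with pytest.raises(ValueError, match="probabilities"):
            categorical_nri(p_ref + 1.0, p_new, out, with_ci=False)


class TestCalibration:
    def test_uncensored_observed_equals_bin_event_fraction(self):
        rng = np.random.default_rng(9)
        n = 500
        p = rng.random(n)
        e = (rng.random(n) < p).astype(int)
        t = np.where(e == 1, 5.0, 20.0)  # all statuses known at horizon 10
        out = SurvivalOutcome(t, e)
        tab = calibration_deciles(p, out, horizon=10.0, n_bins=5).table
        for _, row in tab.iterrows():
            lo = tab["bin"] == row["bin"]
            assert row["n"] == 100
        # per-bin observed equals the raw fraction
        bins = pd.qcut(pd.Series(p).rank(method="first"), 5, labels=False)
        for b in range(5):
            m = (bins == b).to_numpy()
            got = tab.loc[tab["bin"] == b, "observed"].iloc[0]
            assert got == pytest.approx(e[m].mean(), abs=1e-12)

    def test_identical_risks_collapse_to_single_bin(self):
        out = SurvivalOutcome(np.arange(1.0, 51.0), np.ones(50, int))
        tab = calibration_deciles(np.full(50, 0.3), out, horizon=30.0).table
        # ties broken stably: bins still partition all subjects
        assert tab["n"].sum() == 50

    def test_too_few_bins_rejected(self):
        out = SurvivalOutcome(np.arange(1.0, 11.0), np.ones(10, int))
        with pytest.raises(ValueError):
            calibration_deciles(np.linspace(0, 1, 10), out, n_bins=1)


class TestSpearman:
    def test_diagonal_and_monotone_invariance(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.standard_normal(200)})
        df["y"] = np.exp(3.0 * df["x"])
        df["sex"] = "M"
        m = spearman_matrix(["x", "y"], df, sex="M")
        assert m.loc["x", "x"] == 1.0
        assert m.loc["x", "y"] == pytest.approx(1.0)

    def test_needs_two_features(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            spearman_matrix(["x"], df)


class TestIncrementalC:
    def test_null_feature_adds_nothing_redundant_duplicate_adds_zero(self):
        from omicox.riskmodel import ModelSpec
        from omicox.survcox import BarlowWeights
        from omicox.synthdata import SCORE2_VARIABLES

        X, out = weibull_ph_data(12, 1200, [0.4, 0.3, -0.2, 0.2, -0.15, 0.15,
                                            0.2, -0.1, 0.0],
                                 censor_scale=40.0, target_events=0.25)
        df = pd.DataFrame(X[:, :8], columns=SCORE2_VARIABLES)
        df["null_marker"] = X[:, 8]
        # a redundant noisy copy of a base covariate adds ~no discrimination
        df["age_copy"] = df["age"] + 0.1 * np.random.default_rng(0).standard_normal(len(df))
        df["sex"] = "M"
        w = BarlowWeights.unit(len(df))
        d_null = incremental_c("null_marker", ModelSpec(), df, out, w, sex="M")
        assert abs(d_null) < 0.02
        d_dup = incremental_c("age_copy", ModelSpec(), df, out, w, sex="M")
        assert abs(d_dup) < 0.01
        # an exact duplicate is surfaced as a collinearity error
        df["age_exact"] = df["age"]
        with pytest.raises(ValueError, match="collinear"):
            incremental_c("age_exact", ModelSpec(), df, out, w, sex="M")

    def test_true_linear_predictor_improves_c(self):
        from omicox.riskmodel import ModelSpec
        from omicox.survcox import BarlowWeights
        from omicox.synthdata import SCORE2_VARIABLES

        rng = np.random.default_rng(13)
        n = 1000
        X = rng.standard_normal((n, 9))
        lp = X[:, :8] @ np.full(8, 0.15) + 0.9 * X[:, 8]
        T = 10.0 * (-np.log(rng.random(n)) / (0.25 * np.exp(lp))) ** (1 / 1.3)
        out = SurvivalOutcome(np.minimum(T, 10.0), (T <= 10.0).astype(int))
        df = pd.DataFrame(X[:, :8], columns=SCORE2_VARIABLES)
        df["strong"] = X[:, 8]
        df["sex"] = "M"
        w = BarlowWeights.unit(n)
        d = incremental_c("strong", ModelSpec(), df, out, w, sex="M")
        assert d > 0.02
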