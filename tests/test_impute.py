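"""QC filtering and missForest-style imputation."""

import numpy as np
import pandas as pd
import pytest

from omicox.impute import impute_missforest, mean_impute, qc_filter_features


def _toy_qc_table():
    """Five features with constructed missing/below-LOD fractions
    {0.05 miss, 0.20 miss, 0.21 miss, 0.26 below LOD, 0.10 miss}."""
    n = 100
    rng = np.random.default_rng(0)
    cols = {}
    fracs = {"prot_a": 5, "prot_b": 20, "prot_c": 21, "prot_e": 10}
    for name, k in fracs.items():
        v = rng.standard_normal(n)
        v[:k] = np.nan
        cols[name] = v
    lod_col = rng.standard_normal(n)
    lod = np.quantile(lod_col, 0.26)
    cols["prot_d"] = np.maximum(lod_col, lod)
    df = pd.DataFrame(cols)
    return df, {"prot_d": lod}


class TestQcFilter:
    def test_constructed_fixture_drops_exactly_two(self):
        df, lods = _toy_qc_table()
        kept, dropped = qc_filter_features(
            df, 0.20, 0.25, features=list(df.columns), lod_values=lods
        )
        names = {d["feature"] for d in dropped}
        assert names == {"prot_c", "prot_d"}
        reasons = {d["feature"]: d["reason"] for d in dropped}
        assert reasons["prot_c"] == "missingness"
        assert reasons["prot_d"] == "below_lod"
        assert set(kept.columns) == {"prot_a", "prot_b", "prot_e"}

    def test_threshold_is_strict(self):
        # exactly 20% missing is retained; 21% is dropped
        df, lods = _toy_qc_table()
        kept, dropped = qc_filter_features(
            df, 0.20, 0.25, features=list(df.columns), lod_values=lods
        )
        assert "prot_b" in kept.columns
        assert "prot_c" not in kept.columns

    def test_clean_feature_retained(self):
        df = pd.DataFrame({"prot_x": np.arange(50.0)})
        kept, dropped = qc_filter_features(df, 0.2, 0.25)
        assert dropped == [] and "prot_x" in kept.columns

    def test_bad_thresholds_rejected(self):
        df = pd.DataFrame({"prot_x": np.arange(10.0)})
        with pytest.raises(ValueError):
            qc_filter_features(df, 0.0, 0.25)


def _mar_fixture(seed, n=1000, p=5, rho=0.6, miss=0.10):
    """Correlated continuous variables with MAR masking driven by x0."""
    rng = np.random.default_rng(seed)
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    X = rng.standard_normal((n, p)) @ np.linalg.cholesky(corr).T
    full = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
    masked = full.copy()
    from scipy.special import expit

    for j in range(1, p):
        prob = expit(np.log(miss / (1 - miss)) + 0.8 * (X[:, 0] - X[:, 0].mean()))
        prob *= miss / prob.mean()
        m = rng.random(n) < prob
        col = masked[f"v{j}"].to_numpy()
        col[m] = np.nan
        masked[f"v{j}"] = col
    return full, masked


def _nrmse(completed, full, masked):
    num = den = 0.0
    for c in full.columns:
        m = masked[c].isna().to_numpy()
        if not m.any():
            continue
        num += ((completed[c].to_numpy()[m] - full[c].to_numpy()[m]) ** 2).sum()
        den += ((full[c].to_numpy()[m] - full[c].to_numpy()[m].mean()) ** 2).sum()
    return np.sqrt(num / den)


class TestMissForest:
    def test_complete_table_returned_unchanged(self):
        full, _ = _mar_fixture(1)
        res = impute_missforest(full, seed=0)
        assert res.n_iterations == 0
        pd.testing.assert_frame_equal(res.completed_table, full)

    def test_observed_cells_never_altered(self):
        full, masked = _mar_fixture(2)
        res = impute_missforest(masked, seed=0, rf_params={"n_estimators": 20})
        for c in full.columns:
            obs = ~masked[c].isna().to_numpy()
            np.testing.assert_array_equal(
                res.completed_table[c].to_numpy()[obs], masked[c].to_numpy()[obs]
            )

    def test_beats_mean_imputation_on_correlated_mar_data(self):
        full, masked = _mar_fixture(3)
        rf = impute_missforest(masked, seed=1, rf_params={"n_estimators": 50})
        nr_rf = _nrmse(rf.completed_table, full, masked)
        nr_mean = _nrmse(mean_impute(masked), full, masked)
        assert nr_rf < nr_mean

    def test_distributions_preserved_within_five_percent(self):
        full, masked = _mar_fixture(4)
        res = impute_missforest(masked, seed=1, rf_params={"n_estimators": 50})
        for c in full.columns[1:]:
            pre_sd = full[c].std()
            assert abs(res.completed_table[c].mean() - full[c].mean()) < 0.05 * pre_sd
            assert abs(res.completed_table[c].std() - pre_sd) < 0.05 * pre_sd

    def test_all_missing_column_rejected_by_name(self):
        _, masked = _mar_fixture(5)
        masked["v1"] = np.nan
        with pytest.raises(ValueError, match="v1"):
            impute_missforest(masked, seed=0)

    def test_deterministic_given_seed(self):
        _, masked = _mar_fixture(6)
        a = impute_missforest(masked, seed=9, rf_params={"n_estimators": 15})
        b = impute_missforest(masked, seed=9, rf_params={"n_estimators": 15})
        pd.testing.assert_frame_equal(a.completed_table, b.completed_table)

    def test_categorical_column_imputed_with_classifier(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.standard_normal(n)
        cat = (x + 0.5 * rng.standard_normal(n) > 0).astype(float)
        df = pd.DataFrame({"x": x, "smoking": cat})
        m = rng.random(n) < 0.15
        df.loc[m, "smoking"] = np.nan
        res = impute_missforest(df, seed=0, rf_params={"n_estimators": 30})
        vals = res.completed_table["smoking"].unique()
        assert set(vals) <= {0.0, 1.0}

    def test_stopping_trace_shows_first_increase_or_cap(self):
        _, masked = _mar_fixture(8)
        res = impute_missforest(masked, seed=2, max_iter=6,
                                rf_params={"n_estimators": 20})
        trace = [t["continuous"] for t in res.convergence_trace]
        assert len(trace) == res.n_iterations
        if res.n_iterations < 6:
            assert trace[-1] >= trace[-2]  # stopped at the first increase
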