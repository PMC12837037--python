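"""Synthetic cohort generator: copula fidelity, design arithmetic, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, spearmanr

from omicox.synthdata import (
    SimulationConfig,
    default_config,
    draw_case_cohort,
    generate_cohort,
    inject_missingness,
    read_cohort,
    write_cohort,
)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError, match="n_full_cohort"):
        default_config(n_full_cohort=50)
    with pytest.raises(ValueError, match="male_fraction"):
        default_config(male_fraction=1.4)
    with pytest.raises(ValueError, match="horizon"):
        default_config(horizon=0.0)
    with pytest.raises(ValueError, match="missingness"):
        default_config(missingness_rates={"hdl": 1.0})


def test_nonpositive_definite_correlation_rejected_with_pair_names():
    cfg = default_config(
        n_proteins=5,
        correlation_spec=[
            ("prot_001", "prot_002", 0.95),
            ("prot_002", "prot_003", 0.95),
            ("prot_001", "prot_003", -0.95),
        ],
    )
    with pytest.raises(ValueError, match="prot_001"):
        generate_cohort(cfg)


def test_seed_determinism_byte_identical(tmp_path):
    cfg = default_config(n_full_cohort=400, n_proteins=10, seed=5)
    a = generate_cohort(cfg)[0]
    b = generate_cohort(cfg)[0]
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(a, pa)
    write_cohort(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_null_effects_match_baseline_implied_incidence():
    # with all true betas zero the empirical incidence equals the
    # baseline-hazard-implied value up to Monte-Carlo error
    cfg = default_config(
        n_full_cohort=8000, n_proteins=2, n_metabolites=0, include_prs=False,
        true_effects={}, correlation_spec=[], censoring_rate=0.0,
        weibull_scale=(40.0, 40.0), missingness_rates={}, lod_quantiles={},
        seed=11,
    )
    cohort, outcome, truth = generate_cohort(cfg)
    implied = 1.0 - np.exp(-((10.0 / 40.0) ** 1.3))
    assert abs(outcome.event.mean() - implied) < 0.015


def test_planted_spearman_correlation_recovered():
    cfg = default_config(
        n_full_cohort=5000, n_proteins=20, seed=3,
        correlation_spec=[("prot_010", "prot_014", 0.64)],
        missingness_rates={}, lod_quantiles={},
    )
    cohort, _, _ = generate_cohort(cfg)
    rho = spearmanr(cohort["prot_010"], cohort["prot_014"]).statistic
    assert 0.59 <= rho <= 0.69


def test_case_cohort_design_arithmetic_matches_study():
    # default draw: ~1672 sub-cohort + ~79 outside cases -> ~1751 total
    cfg = default_config(seed=2)
    cohort, outcome, _ = generate_cohort(cfg)
    cc = draw_case_cohort(cohort, outcome, cfg.subcohort_fraction, seed=9)
    assert int(cc.in_subcohort.sum()) == round(cfg.subcohort_fraction * len(cohort))
    n_extra = int((~cc.in_subcohort).sum())
    assert 40 <= n_extra <= 120  # ~79 expected
    assert 1700 <= len(cc) <= 1810
    assert np.all(cc.in_subcohort | cc.is_case)
    # sample-level event fraction enriched to ~15%
    assert abs(cc.outcome.event.mean() - 0.154) < 0.03


def test_case_cohort_degenerate_and_determinism():
    cfg = default_config(n_full_cohort=300, n_proteins=2, seed=4)
    cohort, outcome, _ = generate_cohort(cfg)
    full = draw_case_cohort(cohort, outcome, 1.0, seed=1)
    assert len(full) == len(cohort)
    assert full.alpha == 1.0
    a = draw_case_cohort(cohort, outcome, 0.4, seed=7)
    b = draw_case_cohort(cohort, outcome, 0.4, seed=7)
    assert np.array_equal(a.data["id"].to_numpy(), b.data["id"].to_numpy())


def test_case_cohort_requires_cases():
    cfg = default_config(n_full_cohort=200, n_proteins=2, seed=1)
    cohort, outcome, _ = generate_cohort(cfg)
    none = outcome
    none.event[:] = 0
    with pytest.raises(ValueError, match="no cases"):
        draw_case_cohort(cohort, none, 0.5, seed=0)


class TestInjectMissingness:
    def test_zero_rates_leave_table_unchanged(self):
        cfg = default_config(n_full_cohort=300, n_proteins=3, seed=6)
        cohort, _, _ = generate_cohort(cfg)
        out = inject_missingness(cohort, {"hdl": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, cohort)

    def test_rate_of_one_rejected(self):
        cfg = default_config(n_full_cohort=200, n_proteins=2, seed=6)
        cohort, _, _ = generate_cohort(cfg)
        with pytest.raises(ValueError):
            inject_missingness(cohort, {"hdl": 1.0}, seed=1)

    def test_hdl_rate_yields_about_210_missing_at_study_size(self):
        cfg = default_config(seed=8)
        cohort, outcome, _ = generate_cohort(cfg)
        cc = draw_case_cohort(cohort, outcome, cfg.subcohort_fraction, seed=8)
        masked = inject_missingness(cc.data, {"hdl": 0.12}, seed=3)
        n_miss = int(masked["hdl"].isna().sum())
        n, p = len(masked), 0.12
        sd = np.sqrt(n * p * (1 - p))
        assert abs(n_miss - n * p) < 4 * sd

    def test_mar_masking_associates_with_age(self):
        cfg = default_config(n_full_cohort=5000, n_proteins=2, seed=9,
                             missingness_rates={}, lod_quantiles={})
        cohort, _, _ = generate_cohort(cfg)
        masked = inject_missingness(cohort, {"hdl": 0.2}, mechanism="MAR", seed=2)
        is_miss = masked["hdl"].isna().to_numpy()
        old = (cohort["age"] > cohort["age"].median()).to_numpy()
        table = pd.crosstab(is_miss, old)
        assert chi2_contingency(table).pvalue < 0.01

    def test_outcome_and_sex_never_masked(self):
        cfg = default_config(n_full_cohort=300, n_proteins=2, seed=10)
        cohort, _, _ = generate_cohort(cfg)
        out = inject_missingness(
            cohort, {"sex": 0.5, "event": 0.5, "hdl": 0.3}, seed=4
        )
        assert out["sex"].notna().all()
        assert out["event"].notna().all()
        assert out["hdl"].isna().any()


def test_cohort_roundtrip_io(tmp_path):
    cfg = default_config(n_full_cohort=200, n_proteins=3, seed=12)
    cohort, outcome, truth = generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path, truth=truth)
    df, out2 = read_cohort(path)
    assert len(df) == len(cohort)
    np.testing.assert_allclose(out2.time, outcome.time)
    assert (path.parent / "cohort.csv.truth.json").exists()
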