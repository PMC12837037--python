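"""End-to-end two-stage analysis: protein selection, then omics layering.

Stage 1 derives sex-specific protein signatures on the (larger) proteomics
case-cohort sample: QC filtering, missForest imputation, bootstrap-LASSO
stability selection per sex, and an unpenalized refit.  Stage 2 evaluates,
on the nested complete-multi-omics subset, which omics layers (proteins,
metabolites, polygenic score) improve the clinical base model: every
single-layer extension is compared against the base, the largest
statistically significant C-index gain becomes the reference, and remaining
layers are added greedily while the correlated-C test stays significant
(two-sided p < 0.05).  All model fits use Barlow case-cohort weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evalmetrics import (
    calibration_deciles,
    categorical_nri,
    compare_c,
    continuous_nri,
    idi,
    spearman_matrix,
)
from .impute import impute_missforest, qc_filter_features
from .riskmodel import ModelSpec, fit_sex_specific, pooled_risk
from .stabsel import bootstrap_stability_selection, refit_selected
from .survcox import barlow_weights, hazard_ratio_per_sd
from .synthdata import (
    CaseCohortSample,
    SimulationConfig,
    default_config,
    draw_case_cohort,
    generate_cohort,
    inject_missingness,
)

__all__ = [
    "AnalysisConfig",
    "LayerReport",
    "run_stage1_selection",
    "run_stage2_layering",
    "run_full_analysis",
]

_DEFAULT_METABOLITE_SIGNATURE = (
    ("M", ("met_1", "met_2", "met_3", "met_4", "met_5", "met_6")),
    ("F", ("met_1", "met_2", "met_3", "met_7")),
)


@dataclass
class AnalysisConfig:
    """Seeds, sample sizes and tuning constants of the full analysis."""

    simulation: SimulationConfig = field(default_factory=default_config)
    B: int = 1000                  # bootstrap resamples for stability selection
    threshold: float = 0.95        # selection-frequency retention threshold
    n_folds: int = 10
    dfmax: int = 45
    risk_cuts: tuple = (0.15, 0.30)
    horizon: float = 10.0
    seed: int = 0
    rf_params: dict | None = None
    impute_max_iter: int = 10
    n_boot_ci: int = 1000
    metabolite_signature: tuple = _DEFAULT_METABOLITE_SIGNATURE
    qc_max_missing: float = 0.20
    qc_max_below_lod: float = 0.25
    output_dir: str | None = None

    def metabolites_by_sex(self) -> dict:
        return {s: list(f) for s, f in self.metabolite_signature}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        fields = {k: v for k, v in raw.items()}
        if "metabolite_signature" in fields:
            fields["metabolite_signature"] = tuple(
                (s, tuple(f)) for s, f in fields["metabolite_signature"].items()
            )
        return cls(simulation=sim, **fields)


@dataclass
class LayerReport:
    """Greedy layer-addition record for one evaluation scope."""

    scope: str                      # "overall", "M" or "F"
    steps: list                     # accepted additions with their metrics
    evaluations: list               # every candidate comparison per round
    stopping_reason: str            # no-significant-improvement | layers-exhausted

    def __post_init__(self):
        if self.stopping_reason not in (
            "no-significant-improvement", "layers-exhausted"
        ):
            raise ValueError(f"bad stopping reason {self.stopping_reason!r}")
        added = [s["layer"] for s in self.steps]
        if len(set(added)) != len(added):
            raise ValueError("a layer was added twice")


def run_stage1_selection(
    config: AnalysisConfig,
    sample: CaseCohortSample,
    protein_features: list | None = None,
) -> dict:
    """Per-sex bootstrap-LASSO stability selection and unpenalized refit."""
    data = sample.data
    if protein_features is None:
        protein_features = [c for c in data.columns if c.startswith("prot_")]
    weights = barlow_weights(sample)
    out = {}
    for i, sex in enumerate(("M", "F")):
        sel = bootstrap_stability_selection(
            sample,
            features=protein_features,
            B=config.B,
            threshold=config.threshold,
            sex=sex,
            seed=config.seed * 7919 + 101 + i,
            n_folds=config.n_folds,
            dfmax=config.dfmax,
        )
        refit = refit_selected(sel, data, sample.outcome, weights)
        out[sex] = {"selection": sel, "refit": refit}
    return out


def _scope_metrics(r_ref, r_new, outcome, mask, config, with_ci):
    out = outcome.subset(mask)
    comp = compare_c(r_ref[mask], r_new[mask], out)
    cat = categorical_nri(
        r_ref[mask], r_new[mask], out, cuts=config.risk_cuts,
        horizon=config.horizon, n_boot=config.n_boot_ci,
        seed=config.seed + 17, with_ci=with_ci,
    )
    cont = continuous_nri(
        r_ref[mask], r_new[mask], out, horizon=config.horizon,
        n_boot=config.n_boot_ci, seed=config.seed + 18, with_ci=with_ci,
    )
    idi_val, idi_ci = idi(
        r_ref[mask], r_new[mask], out, horizon=config.horizon,
        n_boot=config.n_boot_ci, seed=config.seed + 19, with_ci=with_ci,
    )
    return {
        "c_ref": comp.c_ref, "c_ref_ci": comp.c_ref_ci,
        "c_new": comp.c_new, "c_new_ci": comp.c_new_ci,
        "delta_c": comp.delta_c, "p_value": comp.p_value,
        "nri_total_pct": 100 * cat.nri_total,
        "nri_events_pct": 100 * cat.nri_events,
        "nri_nonevents_pct": 100 * cat.nri_nonevents,
        "nri_total_ci_pct": (
            tuple(100 * x for x in cat.ci_total) if cat.ci_total else None
        ),
        "continuous_nri_pct": 100 * cont.nri_total,
        "idi": idi_val, "idi_ci": idi_ci,
    }


def run_stage2_layering(
    config: AnalysisConfig,
    sample: CaseCohortSample,
    signatures: dict,
    scope: str = "overall",
) -> LayerReport:
    """Greedy sequential omics-layer addition judged by the correlated-C test.

    ``signatures`` maps layer name -> {"M": features, "F": features}.  For a
    single-sex scope the models are fit and compared within that stratum;
    for ``"overall"`` the sex-specific fits are pooled.
    """
    data, outcome = sample.data, sample.outcome
    weights = barlow_weights(sample)
    if scope == "overall":
        mask = np.ones(len(data), dtype=bool)
    elif scope in ("M", "F"):
        mask = (data["sex"] == scope).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")

    def _risks(spec: ModelSpec) -> np.ndarray:
        model = fit_sex_specific(spec, data, outcome, weights)
        return pooled_risk(model, data, config.horizon)

    spec = ModelSpec()
    risks_ref = _risks(spec)
    remaining = [l for l in ("proteins", "metabolites", "prs") if l in signatures]
    steps, evaluations = [], []
    reason = "layers-exhausted"
    round_no = 0
    while remaining:
        round_no += 1
        candidates = []
        for layer in remaining:
            cand_spec = spec.with_layer(layer, signatures[layer])
            r_new = _risks(cand_spec)
            met = _scope_metrics(risks_ref, r_new, outcome, mask, config, with_ci=False)
            met.update({"round": round_no, "layer": layer, "scope": scope})
            evaluations.append(met)
            candidates.append((met, cand_spec, r_new))
        significant = [c for c in candidates if c[0]["p_value"] < 0.05
                       and c[0]["delta_c"] > 0]
        if not significant:
            reason = "no-significant-improvement"
            break
        best_met, best_spec, best_risks = max(
            significant, key=lambda c: c[0]["delta_c"]
        )
        accepted = dict(best_met)
        accepted.update(
            _scope_metrics(risks_ref, best_risks, outcome, mask, config, with_ci=True)
        )
        steps.append(accepted)
        spec, risks_ref = best_spec, best_risks
        remaining.remove(best_met["layer"])
    return LayerReport(scope=scope, steps=steps, evaluations=evaluations,
                       stopping_reason=reason)


def _stage2_sample(cohort, cc_sample: CaseCohortSample, data) -> CaseCohortSample:
    """Nested complete-multi-omics subset with its own sampling fraction."""
    mo = data["in_multiomics"].to_numpy() == 1
    full_mo = cohort["in_multiomics"].to_numpy() == 1
    # the multi-omics flag is independent of sub-cohort membership, so the
    # stage-2 sub-cohort is a simple random sample of the stage-2 full cohort
    sub_ids = set(data.loc[mo & cc_sample.in_subcohort, "id"])
    alpha2 = len(sub_ids) / int(full_mo.sum())
    d2 = data.loc[mo].reset_index(drop=True)
    d2.attrs.update(data.attrs)
    return CaseCohortSample(
        data=d2,
        outcome=cc_sample.outcome.subset(mo),
        in_subcohort=cc_sample.in_subcohort[mo],
        is_case=cc_sample.is_case[mo],
        alpha=alpha2,
    )


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Simulate, select, layer, and evaluate; returns the full report bundle.

    Deterministic given the config.  When ``config.output_dir`` is set the
    tables are also written as CSV/JSON with a manifest keyed by the config
    hash.
    """
    bundle: dict = {"config_hash": config.config_hash()}
    sim = replace(config.simulation, seed=config.simulation.seed + config.seed)
    cohort, outcome, truth = generate_cohort(sim)
    cc = draw_case_cohort(cohort, outcome, sim.subcohort_fraction, seed=sim.seed + 1)

    masked = inject_missingness(
        cc.data, sim.missingness_rates, mechanism="MAR", seed=sim.seed + 2
    )
    qc_table, dropped = qc_filter_features(
        masked, config.qc_max_missing, config.qc_max_below_lod,
        lod_values=truth.lod_values,
    )
    bundle["qc_dropped"] = dropped
    imputed = impute_missforest(
        qc_table, max_iter=config.impute_max_iter, seed=sim.seed + 3,
        rf_params=config.rf_params,
    )
    data = imputed.completed_table
    sample = CaseCohortSample(
        data=data, outcome=cc.outcome, in_subcohort=cc.in_subcohort,
        is_case=cc.is_case, alpha=cc.alpha,
    )
    bundle["imputation"] = {
        "n_iterations": imputed.n_iterations, "oob_error": imputed.oob_error,
    }
    bundle["sample_info"] = {
        "n": len(sample),
        "n_subcohort": int(sample.in_subcohort.sum()),
        "n_cases": int(sample.is_case.sum()),
        "event_fraction": float(sample.outcome.event.mean()),
        "alpha": sample.alpha,
    }

    # ---- stage 1: sex-specific protein signatures on the proteomics sample
    stage1 = run_stage1_selection(config, sample)
    bundle["stage1"] = stage1
    protein_signature = {sex: stage1[sex]["selection"].retained for sex in ("M", "F")}
    bundle["protein_signature"] = protein_signature

    weights = barlow_weights(sample)
    spec0 = ModelSpec()
    spec_prot = spec0.with_layer("proteins", protein_signature)
    base_model = fit_sex_specific(spec0, data, sample.outcome, weights)
    prot_model = fit_sex_specific(spec_prot, data, sample.outcome, weights)
    r_base = pooled_risk(base_model, data, config.horizon)
    r_prot = pooled_risk(prot_model, data, config.horizon)
    perf = {}
    for scope in ("M", "F", "overall"):
        mask = (
            np.ones(len(data), dtype=bool)
            if scope == "overall"
            else (data["sex"] == scope).to_numpy()
        )
        perf[scope] = _scope_metrics(
            r_base, r_prot, sample.outcome, mask, config, with_ci=True
        )
    bundle["proteomics_performance"] = perf
    bundle["calibration"] = calibration_deciles(
        r_prot, sample.outcome, config.horizon
    ).table

    # ---- stage 2: sequential multi-omics layering on the nested subset
    sample2 = _stage2_sample(cohort, cc, data)
    signatures = {
        "proteins": protein_signature,
        "metabolites": config.metabolites_by_sex(),
        "prs": {"M": ["prs"], "F": ["prs"]},
    }
    bundle["stage2"] = {
        scope: run_stage2_layering(config, sample2, signatures, scope)
        for scope in ("overall", "M", "F")
    }

    # ---- per-biomarker associations (HR per SD, adjusted) and correlations
    weights2 = barlow_weights(sample2)
    assoc_rows = []
    for sex in ("M", "F"):
        biomarkers = (
            list(protein_signature[sex])
            + config.metabolites_by_sex()[sex]
            + (["prs"] if "prs" in sample2.data.columns else [])
        )
        for feat in biomarkers:
            table, outc, wts = (
                (data, sample.outcome, weights)
                if feat.startswith("prot_")
                else (sample2.data, sample2.outcome, weights2)
            )
            try:
                a = hazard_ratio_per_sd(feat, table, outc, wts, sex=sex)
            except ValueError:
                continue
            assoc_rows.append(
                {"feature": feat, "sex": sex, "hr_per_sd": a.hazard_ratio,
                 "ci_low": a.ci_low, "ci_high": a.ci_high, "p": a.p_value}
            )
        corr_feats = sorted(set(biomarkers))
        if len(corr_feats) >= 2:
            bundle[f"correlation_{sex}"] = spearman_matrix(
                corr_feats, sample2.data, sex=sex
            )
    bundle["associations"] = pd.DataFrame(assoc_rows)

    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": bundle["config_hash"], "artifacts": []}

    def _save_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["artifacts"].append(name)

    freqs = []
    for sex in ("M", "F"):
        sel = bundle["stage1"][sex]["selection"]
        f = sel.frequencies.rename("frequency").rename_axis("feature").reset_index()
        f["sex"] = sex
        f["retained"] = f["feature"].isin(sel.retained)
        freqs.append(f)
        coefs = bundle["stage1"][sex]["refit"].coef_table().rename_axis("term").reset_index()
        _save_df(coefs, f"stage1_refit_coefficients_{sex}.csv")
    _save_df(pd.concat(freqs), "selection_frequencies.csv")

    rows = []
    for scope, metrics in bundle["proteomics_performance"].items():
        rows.append({"scope": scope, **{k: v for k, v in metrics.items()
                                        if not isinstance(v, tuple)}})
    _save_df(pd.DataFrame(rows), "proteomics_model_performance.csv")
    _save_df(bundle["calibration"], "calibration_deciles.csv")

    layer_rows = []
    for scope, report in bundle["stage2"].items():
        for ev in report.evaluations:
            layer_rows.append({k: v for k, v in ev.items() if not isinstance(v, tuple)})
    _save_df(pd.DataFrame(layer_rows), "stage2_layering.csv")
    if len(bundle["associations"]):
        _save_df(bundle["associations"], "biomarker_associations.csv")
    for sex in ("M", "F"):
        key = f"correlation_{sex}"
        if key in bundle:
            bundle[key].to_csv(out / f"{key}.csv")
            manifest["artifacts"].append(f"{key}.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
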