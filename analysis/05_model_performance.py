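"""Discrimination, reclassification and calibration of the extended models.

Fits the clinical base model and the proteomics-extended model on the
case-cohort sample, then reports — for males, females and overall — the
C-index of each model with 95% CI, the correlated-C p-value, categorical
NRI (risk categories 0-15%, >15-30%, >30%), continuous NRI and IDI, plus a
decile calibration table for the extended model.

Usage: python analysis/05_model_performance.py [--seed N]
"""

import argparse
import importlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))

from omicox.evalmetrics import calibration_deciles
from omicox.pipeline import AnalysisConfig, _scope_metrics
from omicox.riskmodel import ModelSpec, fit_sex_specific, pooled_risk
from omicox.survcox import barlow_weights


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    stage1 = importlib.import_module("03_protein_selection")
    sample = stage1.load_sample(args.results)
    signature = json.loads((args.results / "protein_signature.json").read_text())
    config = AnalysisConfig(seed=args.seed)

    weights = barlow_weights(sample)
    spec0 = ModelSpec()
    spec1 = spec0.with_layer("proteins", signature)
    base = fit_sex_specific(spec0, sample.data, sample.outcome, weights)
    prot = fit_sex_specific(spec1, sample.data, sample.outcome, weights)
    r0 = pooled_risk(base, sample.data, config.horizon)
    r1 = pooled_risk(prot, sample.data, config.horizon)

    rows = []
    for scope in ("M", "F", "overall"):
        mask = (
            np.ones(len(sample.data), dtype=bool)
            if scope == "overall"
            else (sample.data["sex"] == scope).to_numpy()
        )
        m = _scope_metrics(r0, r1, sample.outcome, mask, config, with_ci=True)
        print(
            f"{scope:>7}: C {m['c_ref']:.3f} -> {m['c_new']:.3f} "
            f"(dC={m['delta_c']:+.3f}, p={m['p_value']:.2g}); "
            f"NRI {m['nri_total_pct']:.1f}%, cNRI {m['continuous_nri_pct']:.1f}%, "
            f"IDI {m['idi']:.3f}"
        )
        rows.append({"scope": scope, **{k: v for k, v in m.items()
                                        if not isinstance(v, tuple)}})
    pd.DataFrame(rows).to_csv(args.results / "model_performance.csv", index=False)

    cal = calibration_deciles(r1, sample.outcome, config.horizon)
    cal.table.to_csv(args.results / "calibration_deciles.csv", index=False)
    print("\ncalibration (proteomics-extended model):")
    print(cal.table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
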