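"""Per-biomarker associations with 10-year MACE and biomarker correlations.

For every selected protein, the fixed metabolite panel and the polygenic
score: hazard ratio per one (weighted) SD increment from a Barlow-weighted
Cox model adjusted for the clinical base variables, per sex.  Also writes
the per-sex Spearman correlation matrices of the selected biomarkers.

Usage: python analysis/06_biomarker_associations.py [--seed N]
"""

import argparse
import importlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))

from omicox.evalmetrics import spearman_matrix
from omicox.pipeline import AnalysisConfig
from omicox.survcox import barlow_weights, hazard_ratio_per_sd


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

    rows = []
    for sex in ("M", "F"):
        biomarkers = list(signature[sex]) + config.metabolites_by_sex()[sex] + ["prs"]
        for feat in biomarkers:
            try:
                a = hazard_ratio_per_sd(feat, sample.data, sample.outcome, weights, sex=sex)
            except (ValueError, KeyError):
                continue
            rows.append(
                {"feature": feat, "sex": sex, "hr_per_sd": a.hazard_ratio,
                 "ci_low": a.ci_low, "ci_high": a.ci_high, "p": a.p_value}
            )
        feats = sorted(set(biomarkers) & set(sample.data.columns))
        if len(feats) >= 2:
            corr = spearman_matrix(feats, sample.data, sex=sex)
            corr.to_csv(args.results / f"correlation_{sex}.csv")
            off = corr.where(~np.eye(len(corr), dtype=bool))
            print(f"sex={sex}: strongest biomarker correlation "
                  f"{off.abs().max().max():.2f}")
    tab = pd.DataFrame(rows)
    tab.to_csv(args.results / "biomarker_associations.csv", index=False)
    print(tab.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
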