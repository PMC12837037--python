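"""Stage 2: sequential multi-omics layer addition on the nested subset.

Evaluates, on the complete-multi-omics subset of the case-cohort sample,
which omics layers (stage-1 protein signatures, the fixed 7-metabolite
panel, the polygenic score) improve the clinical base model.  Each
single-layer extension is compared to the base by the correlated-C test;
the largest significant gain becomes the reference and remaining layers are
added greedily while the improvement stays significant (p < 0.05).  Run
overall (pooled sex-specific risks) and separately per sex.

Usage: python analysis/04_omics_layering.py [--seed N]
"""

import argparse
import importlib
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))

from omicox.pipeline import AnalysisConfig, run_stage2_layering
from omicox.synthdata import CaseCohortSample


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    stage1 = importlib.import_module("03_protein_selection")
    sample = stage1.load_sample(args.results)
    signature = json.loads((args.results / "protein_signature.json").read_text())

    # nested multi-omics subset keeps the case-cohort structure; the
    # multi-omics flag is independent of the sub-cohort draw, so the
    # sampling fraction carries over
    mo = sample.data["in_multiomics"].to_numpy() == 1
    d2 = sample.data.loc[mo].reset_index(drop=True)
    sample2 = CaseCohortSample(
        data=d2,
        outcome=sample.outcome.subset(mo),
        in_subcohort=sample.in_subcohort[mo],
        is_case=sample.is_case[mo],
        alpha=sample.alpha,
    )
    print(f"multi-omics subset: n={len(sample2)}, cases={int(sample2.is_case.sum())}")

    config = AnalysisConfig(seed=args.seed)
    signatures = {
        "proteins": signature,
        "metabolites": config.metabolites_by_sex(),
        "prs": {"M": ["prs"], "F": ["prs"]},
    }
    rows = []
    for scope in ("overall", "M", "F"):
        report = run_stage2_layering(config, sample2, signatures, scope)
        added = [s["layer"] for s in report.steps]
        print(f"\nscope={scope}: added layers {added} ({report.stopping_reason})")
        for ev in report.evaluations:
            print(
                f"  round {ev['round']}: +{ev['layer']:<12} "
                f"dC={ev['delta_c']:+.4f} p={ev['p_value']:.3f}"
            )
            rows.append({k: v for k, v in ev.items() if not isinstance(v, tuple)})
    pd.DataFrame(rows).to_csv(args.results / "stage2_layering.csv", index=False)


if __name__ == "__main__":
    main()
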