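"""Omics QC filtering and missForest-style single imputation.

QC removes features whose missingness or below-detection-limit fraction
strictly exceeds the configured thresholds (defaults: 20% missing, 25%
below LOD).  Imputation is iterative chained equations with random forests:
initialize missing entries with mean/mode, then cyclically re-predict each
incomplete variable from all others (random forests from scikit-learn),
visiting variables in order of ascending missingness, and stop at the first
iteration where the normalized change statistic increases, returning the
previous iterate — the canonical missForest stopping rule.  Observed cells
are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "ImputationResult",
    "qc_filter_features",
    "impute_missforest",
]

#: Columns that are never imputed and never used as predictors.
_META_COLUMNS = {"id", "time_years", "event", "in_subcohort", "in_multiomics"}


def qc_filter_features(
    table: pd.DataFrame,
    max_missing: float = 0.20,
    max_below_lod: float = 0.25,
    features: list | None = None,
    lod_values: dict | None = None,
) -> tuple[pd.DataFrame, list]:
    """Drop omics features with excess missingness or below-LOD values.

    A feature is dropped when its missing fraction strictly exceeds
    ``max_missing`` or its fraction of (non-missing) values at or below the
    detection limit strictly exceeds ``max_below_lod``.  Returns the filtered
    table and a report listing each dropped feature with the reason.
    """
    for name, v in [("max_missing", max_missing), ("max_below_lod", max_below_lod)]:
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if features is None:
        features = [c for c in table.columns if c.startswith("prot_")]
    if lod_values is None:
        lod_values = table.attrs.get("lod_values", {})

    dropped = []
    for feat in features:
        col = table[feat]
        miss_frac = float(col.isna().mean())
        obs = col.dropna()
        lod = lod_values.get(feat)
        lod_frac = float((obs <= lod).mean()) if (lod is not None and len(obs)) else 0.0
        if miss_frac > max_missing:
            dropped.append(
                {"feature": feat, "reason": "missingness", "fraction": miss_frac}
            )
        elif lod_frac > max_below_lod:
            dropped.append(
                {"feature": feat, "reason": "below_lod", "fraction": lod_frac}
            )
    out = table.drop(columns=[d["feature"] for d in dropped])
    out.attrs.update(table.attrs)
    return out, dropped


@dataclass
class ImputationResult:
    completed_table: pd.DataFrame
    n_iterations: int
    convergence_trace: list = field(default_factory=list)
    oob_error: dict = field(default_factory=dict)


def _is_categorical(col: pd.Series) -> bool:
    obs = col.dropna()
    if obs.dtype == object:
        return True
    vals = obs.unique()
    return len(vals) <= 10 and np.allclose(vals, np.round(vals))


def impute_missforest(
    table: pd.DataFrame,
    max_iter: int = 10,
    seed: int = 0,
    rf_params: dict | None = None,
    predictors: list | None = None,
) -> ImputationResult:
    """Single imputation by iterative random-forest chained equations.

    ``predictors`` limits the columns used as features and imputation targets
    (default: every column except identifiers, design flags and the outcome;
    sex is encoded 0/1 and used as a predictor).  Deterministic given
    ``seed``.
    """
    rf_params = {"n_estimators": 100, **(rf_params or {})}
    work = table.copy()
    work.attrs.update(table.attrs)

    if predictors is None:
        predictors = [c for c in table.columns if c not in _META_COLUMNS and c != "sex"]
    targets = [c for c in predictors if table[c].isna().any()]
    for c in targets:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
    if not targets:
        return ImputationResult(work, 0)

    # design matrix: predictors + sex encoded numerically
    cols = list(predictors)
    Xd = work[cols].astype(float).copy()
    if "sex" in table.columns:
        Xd["_sex_male"] = (table["sex"] == "M").astype(float)
    masks = {c: table[c].isna().to_numpy() for c in targets}
    categorical = {c: _is_categorical(table[c]) for c in targets}

    # mean/mode initialization
    for c in targets:
        obs = table[c].dropna()
        fill = obs.mode().iloc[0] if categorical[c] else obs.mean()
        Xd.loc[masks[c], c] = fill

    # ascending missingness order
    order = sorted(targets, key=lambda c: masks[c].sum())

    prev = Xd.copy()
    best = Xd.copy()
    trace = []
    oob = {}
    prev_stat = None
    n_done = 0
    rng = np.random.default_rng(seed)
    for it in range(1, max_iter + 1):
        for c in order:
            m = masks[c]
            feat_cols = [f for f in Xd.columns if f != c]
            Xtr = Xd.loc[~m, feat_cols].to_numpy()
            ytr = Xd.loc[~m, c].to_numpy()
            Xmis = Xd.loc[m, feat_cols].to_numpy()
            rs = int(rng.integers(0, 2**31 - 1))
            import warnings as _warnings

            with _warnings.catch_warnings():
                # OOB estimates can be unreliable with few trees; that only
                # degrades the reported error estimate, not the imputation
                _warnings.filterwarnings("ignore", message=".*OOB.*")
                if categorical[c]:
                    rf = RandomForestClassifier(
                        random_state=rs, oob_score=True, **rf_params
                    )
                    rf.fit(Xtr, ytr.astype(int))
                    Xd.loc[m, c] = rf.predict(Xmis).astype(float)
                    oob[c] = 1.0 - float(rf.oob_score_)  # falsely classified
                else:
                    rf = RandomForestRegressor(
                        random_state=rs, oob_score=True, **rf_params
                    )
                    rf.fit(Xtr, ytr)
                    Xd.loc[m, c] = rf.predict(Xmis)
                    # missForest-style NRMSE estimate from out-of-bag R^2
                    oob[c] = float(np.sqrt(max(0.0, 1.0 - rf.oob_score_)))

        # normalized change statistics over imputed cells
        num_c = den_c = 0.0
        dis = tot = 0
        for c in order:
            m = masks[c]
            new = Xd.loc[m, c].to_numpy()
            old = prev.loc[m, c].to_numpy()
            if categorical[c]:
                dis += int((new != old).sum())
                tot += int(m.sum())
            else:
                num_c += float(((new - old) ** 2).sum())
                den_c += float((new**2).sum())
        stat = {"iteration": it}
        parts = []
        if den_c > 0:
            stat["continuous"] = num_c / den_c
            parts.append(stat["continuous"])
        if tot > 0:
            stat["categorical"] = dis / tot
            parts.append(stat["categorical"])
        trace.append(stat)
        n_done = it

        if prev_stat is not None and all(
            s >= p for s, p in zip(parts, prev_stat)
        ):
            # first increase: return the previous iterate
            Xd = best
            break
        prev_stat = parts
        best = Xd.copy()
        prev = Xd.copy()

    for c in targets:
        work[c] = work[c].astype(float)
        work.loc[masks[c], c] = Xd.loc[masks[c], c]
    return ImputationResult(work, n_done, trace, oob)


def mean_impute(table: pd.DataFrame, columns: list | None = None) -> pd.DataFrame:
    """Column-mean/mode imputation (comparison baseline)."""
    out = table.copy()
    columns = columns or [c for c in table.columns if c not in _META_COLUMNS and c != "sex"]
    for c in columns:
        if not out[c].isna().any():
            continue
        obs = out[c].dropna()
        fill = obs.mode().iloc[0] if _is_categorical(out[c]) else obs.mean()
        out[c] = out[c].fillna(fill)
    return out
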