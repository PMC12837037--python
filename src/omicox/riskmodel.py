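"""Sex-specific risk model assembly: clinical base + configurable omics layers.

The base model is the eight-variable clinical risk set (age, smoking status,
SBP, total cholesterol, HDL-C, age at diabetes diagnosis, HbA1c, eGFR),
refit in-cohort with sex handled by stratification: one weighted Cox fit per
sex.  Omics layers (proteins, metabolites, polygenic score) extend the base
with per-sex feature lists, and pooled 10-year risks are produced by scoring
every subject with their own sex's model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survcox import BarlowWeights, FittedCox, fit_cox, predict_absolute_risk
from .synthdata import SCORE2_VARIABLES, SurvivalOutcome

__all__ = ["ModelSpec", "SexSpecificModel", "fit_single_sex", "fit_sex_specific", "pooled_risk"]

LAYERS = ("proteins", "metabolites", "prs")


@dataclass(frozen=True)
class ModelSpec:
    """Base variables plus an ordered set of omics layers with per-sex features."""

    layers: tuple = ()
    layer_features: tuple = ()  # tuple of (layer, (("M", feats), ("F", feats)))

    base_variables: tuple = tuple(SCORE2_VARIABLES)

    def __post_init__(self):
        if tuple(self.base_variables) != tuple(SCORE2_VARIABLES):
            raise ValueError("the clinical base variable list is fixed")
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("layers must be unique")
        for layer in self.layers:
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r}")

    def _features(self) -> dict:
        return {layer: dict(sexes) for layer, sexes in self.layer_features}

    def columns(self, sex: str) -> list:
        cols = list(self.base_variables)
        feats = self._features()
        for layer in self.layers:
            cols += [f for f in feats.get(layer, {}).get(sex, []) if f not in cols]
        return cols

    def with_layer(self, layer: str, features_by_sex: dict) -> "ModelSpec":
        if layer in self.layers:
            raise ValueError(f"layer {layer!r} already present")
        lf = self.layer_features + (
            (layer, tuple((s, tuple(f)) for s, f in features_by_sex.items())),
        )
        return replace(self, layers=self.layers + (layer,), layer_features=lf)

    def to_json(self) -> str:
        return json.dumps(
            {"layers": list(self.layers),
             "layer_features": [[l, {s: list(f) for s, f in sexes}]
                                for l, sexes in self.layer_features]}
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(
            layers=tuple(d["layers"]),
            layer_features=tuple(
                (l, tuple((s_, tuple(f)) for s_, f in sexes.items()))
                for l, sexes in d["layer_features"]
            ),
        )


@dataclass
class SexSpecificModel:
    male: FittedCox
    female: FittedCox
    spec: ModelSpec

    def __post_init__(self):
        for fit in (self.male, self.female):
            if not fit.converged:
                raise ValueError("sex-specific fit did not converge")

    def fit_for(self, sex: str) -> FittedCox:
        return self.male if sex == "M" else self.female


def fit_single_sex(
    columns: list,
    data: pd.DataFrame,
    outcome: SurvivalOutcome,
    weights: BarlowWeights | None = None,
) -> FittedCox:
    return fit_cox(data[list(columns)], outcome, weights)


def fit_sex_specific(
    spec: ModelSpec,
    data: pd.DataFrame,
    outcome: SurvivalOutcome,
    weights: BarlowWeights | None = None,
) -> SexSpecificModel:
    """Independent weighted Cox fits per sex on the model spec's column set."""
    fits = {}
    for sex in ("M", "F"):
        keep = (data["sex"] == sex).to_numpy()
        if outcome.event[keep].sum() == 0:
            raise ValueError(f"stratum {sex!r} has no events")
        fits[sex] = fit_single_sex(
            spec.columns(sex),
            data.loc[keep].reset_index(drop=True),
            outcome.subset(keep),
            weights.subset(keep) if weights is not None else None,
        )
    return SexSpecificModel(male=fits["M"], female=fits["F"], spec=spec)


def pooled_risk(
    model: SexSpecificModel, data: pd.DataFrame, horizon: float = 10.0
) -> np.ndarray:
    """Per-subject 10-year absolute risk, each subject scored by their sex's fit."""
    sexes = data["sex"].to_numpy()
    if not np.all(np.isin(sexes, ("M", "F"))):
        raise ValueError("unknown sex codes present")
    risk = np.empty(len(data))
    for sex in ("M", "F"):
        m = sexes == sex
        if not m.any():
            continue
        fit = model.fit_for(sex)
        risk[m] = predict_absolute_risk(
            fit, data.loc[m, model.spec.columns(sex)], horizon
        )
    return risk
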