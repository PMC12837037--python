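"""Bootstrap stability selection around the penalized weighted Cox model.

For each of ``B`` bootstrap resamples of the case-cohort sample (stratified
jointly on case status and sub-cohort membership, so the design composition
and the Barlow sampling fraction are preserved), the regularization strength
is re-selected by 10-fold cross-validation and the active set at lambda_min
is recorded.  Features selected in at least a threshold fraction (default
95%) of resamples are retained and refit unpenalized alongside the clinical
base covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxnet import PenaltySpec, cv_lambda_min
from .survcox import FittedCox, barlow_weights, fit_cox
from .synthdata import SCORE2_VARIABLES, CaseCohortSample, SurvivalOutcome

__all__ = [
    "SelectionResult",
    "as_full_cohort_sample",
    "bootstrap_stability_selection",
    "refit_selected",
]


@dataclass
class SelectionResult:
    """Per-feature bootstrap selection frequencies and the retained set."""

    frequencies: pd.Series      # feature -> selection frequency in [0, 1]
    B: int
    threshold: float
    retained: list
    sex: str | None
    seed: int
    lambda_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    base_covariates: list = field(default_factory=lambda: list(SCORE2_VARIABLES))
    n_redraws: int = 0

    def __post_init__(self):
        expect = [f for f in self.frequencies.index
                  if self.frequencies[f] >= self.threshold - 1e-12]
        if sorted(expect) != sorted(self.retained):
            raise ValueError("retained set inconsistent with frequencies/threshold")


def as_full_cohort_sample(data: pd.DataFrame, outcome: SurvivalOutcome) -> CaseCohortSample:
    """Wrap a fully observed cohort as a degenerate case-cohort sample (alpha=1)."""
    n = len(data)
    return CaseCohortSample(
        data=data,
        outcome=outcome,
        in_subcohort=np.ones(n, dtype=bool),
        is_case=outcome.event.astype(bool),
        alpha=1.0,
    )


def _resample_indices(rng, is_case, in_subcohort, stratified):
    n = len(is_case)
    if not stratified:
        return rng.integers(0, n, size=n)
    idx = []
    strata = (is_case.astype(int) * 2 + in_subcohort.astype(int))
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        idx.append(members[rng.integers(0, len(members), size=len(members))])
    return np.concatenate(idx)


def bootstrap_stability_selection(
    sample: CaseCohortSample,
    features: list,
    base_covariates: list | None = None,
    B: int = 1000,
    threshold: float = 0.95,
    sex: str | None = None,
    seed: int = 0,
    stratified: bool = True,
    n_folds: int = 10,
    dfmax: int | None = 45,
    max_redraws: int = 50,
) -> SelectionResult:
    """Selection frequencies of ``features`` over ``B`` bootstrap LASSO fits.

    The clinical ``base_covariates`` are force-included (penalty factor 0) in
    every fit; only ``features`` are penalized and counted.  ``sex`` (``"M"``
    or ``"F"``) restricts to that stratum before resampling.  Deterministic
    given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    base_covariates = list(SCORE2_VARIABLES) if base_covariates is None else list(base_covariates)

    data, outcome = sample.data, sample.outcome
    is_case, in_sub = sample.is_case, sample.in_subcohort
    if sex is not None:
        keep = (data["sex"] == sex).to_numpy()
        data = data.loc[keep].reset_index(drop=True)
        outcome = outcome.subset(keep)
        is_case, in_sub = is_case[keep], in_sub[keep]
    n = len(data)
    n_events = int(outcome.event.sum())
    if n_events < 30:
        import warnings

        warnings.warn(
            f"stratum has only {n_events} events; selection may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    cols = base_covariates + list(features)
    X = data[cols].to_numpy(dtype=float)
    pf = np.r_[np.zeros(len(base_covariates)), np.ones(len(features))]
    n_sub0 = int(in_sub.sum())

    counts = np.zeros(len(features))
    lam_mins = np.empty(B)
    n_redraws = 0
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * B) % (2**31 - 1)
    for b in range(B):
        rng = np.random.default_rng(int(child_seeds[2 * b]))
        for attempt in range(max_redraws + 1):
            idx = _resample_indices(rng, is_case, in_sub, stratified)
            if outcome.event[idx].sum() > 0:
                break
            n_redraws += 1
        else:
            raise RuntimeError("exceeded redraw cap: resamples without events")

        out_b = outcome.subset(idx)
        sub_b = in_sub[idx]
        alpha_b = min(1.0, sample.alpha * sub_b.sum() / max(n_sub0, 1))
        cc_b = CaseCohortSample(
            data=pd.DataFrame(index=range(len(idx))),  # weights need flags only
            outcome=out_b,
            in_subcohort=sub_b,
            is_case=is_case[idx],
            alpha=alpha_b,
        )
        w_b = barlow_weights(cc_b)
        cv = cv_lambda_min(
            pd.DataFrame(X[idx], columns=cols),
            out_b,
            w_b,
            PenaltySpec(penalty_factor=pf, dfmax=dfmax),
            n_folds=n_folds,
            seed=int(child_seeds[2 * b + 1]),
        )
        lam_mins[b] = cv.lambda_min
        active = set(cv.path.active_set(cv.lambda_min_index))
        for k, f in enumerate(features):
            if f in active:
                counts[k] += 1.0

    freq = pd.Series(counts / B, index=list(features), name="selection_frequency")
    retained = [f for f in features if freq[f] >= threshold - 1e-12]
    return SelectionResult(
        frequencies=freq,
        B=B,
        threshold=threshold,
        retained=retained,
        sex=sex,
        seed=seed,
        lambda_min=lam_mins,
        base_covariates=base_covariates,
        n_redraws=n_redraws,
    )


def refit_selected(
    selection: SelectionResult,
    data: pd.DataFrame,
    outcome: SurvivalOutcome,
    weights=None,
) -> FittedCox:
    """Unpenalized weighted Cox on base covariates + retained features.

    Restricted to the selection's sex stratum when one was used; with an
    empty retained set this is exactly the base-covariates-only model.
    """
    if selection.sex is not None:
        keep = (data["sex"] == selection.sex).to_numpy()
        data = data.loc[keep].reset_index(drop=True)
        outcome = outcome.subset(keep)
        if weights is not None:
            weights = weights.subset(keep)
    cols = selection.base_covariates + selection.retained
    return fit_cox(data[cols], outcome, weights)
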