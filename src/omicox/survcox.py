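"""Barlow-weighted Cox partial-likelihood machinery for case-cohort designs.

Implements the weighted Breslow partial likelihood with Barlow's original
inverse-probability weighting: non-case sub-cohort members carry weight
1/alpha throughout follow-up, sub-cohort cases carry 1/alpha before their
event and 1 at it, and cases outside the sub-cohort enter the risk set only
at their own failure time (pre-event weight 0, at-event weight 1).  With
alpha = 1 everything reduces to the ordinary unweighted Cox model.

Estimation is Newton-Raphson with step-halving; model-based and robust
(sandwich, score-residual based) standard errors are both reported, the
latter being the valid choice under the weighted pseudo-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import SurvivalOutcome, CaseCohortSample

__all__ = [
    "BarlowWeights",
    "FittedCox",
    "AssociationResult",
    "barlow_weights",
    "fit_cox",
    "predict_absolute_risk",
    "hazard_ratio_per_sd",
]


@dataclass
class BarlowWeights:
    """Per-subject pre-event and at-event risk-set weights."""

    pre_event: np.ndarray
    at_event: np.ndarray

    def __post_init__(self):
        self.pre_event = np.asarray(self.pre_event, dtype=float)
        self.at_event = np.asarray(self.at_event, dtype=float)
        if np.any(self.pre_event < 0) or np.any(self.at_event < 0):
            raise ValueError("weights must be non-negative")

    @classmethod
    def unit(cls, n: int) -> "BarlowWeights":
        return cls(np.ones(n), np.ones(n))

    def subset(self, idx) -> "BarlowWeights":
        return BarlowWeights(self.pre_event[idx], self.at_event[idx])

    def averaging_weight(self) -> np.ndarray:
        """Subject-level weight for means/SDs: pre-event weight, except for
        cases outside the sub-cohort which represent only themselves."""
        return np.where(self.pre_event > 0, self.pre_event, self.at_event)


def barlow_weights(sample: CaseCohortSample) -> BarlowWeights:
    """Inverse-probability Barlow weights for a case-cohort sample."""
    a = sample.alpha
    if not (0.0 < a <= 1.0):
        raise ValueError(f"sampling fraction alpha must be in (0,1], got {a}")
    pre = np.where(sample.in_subcohort, 1.0 / a, 0.0)
    at = np.where(sample.is_case, 1.0, pre)
    return BarlowWeights(pre, at)


@dataclass
class FittedCox:
    """A converged weighted Cox fit with its Breslow baseline hazard."""

    names: list
    beta: np.ndarray
    se: np.ndarray                 # model-based (inverse information)
    robust_se: np.ndarray          # sandwich
    loglik: float
    baseline_times: np.ndarray     # increasing event times
    baseline_cumhaz: np.ndarray    # H0 at those times (right-continuous step)
    center: np.ndarray             # weighted covariate means used for centering
    converged: bool
    n_iter: int
    max_time: float
    messages: list = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        z = self.beta / self.robust_se
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": np.exp(self.beta),
                "se": self.se,
                "robust_se": self.robust_se,
                "hr_ci_low": np.exp(self.beta - 1.959963984540054 * self.robust_se),
                "hr_ci_high": np.exp(self.beta + 1.959963984540054 * self.robust_se),
                "p": p,
            },
            index=self.names,
        )

    def cumhaz_at(self, t: float) -> float:
        i = np.searchsorted(self.baseline_times, t, side="right")
        return 0.0 if i == 0 else float(self.baseline_cumhaz[i - 1])

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.names)
        return (X - self.center) @ self.beta


@dataclass
class AssociationResult:
    """Per-SD hazard ratio for one feature, adjusted for the base variables."""

    feature: str
    sex: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int

    def __post_init__(self):
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def _as_matrix(X, names=None):
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X[list(names)]
        return np.ascontiguousarray(X.to_numpy(dtype=float))
    return np.ascontiguousarray(np.asarray(X, dtype=float))


def _column_names(X, p):
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return [f"x{j}" for j in range(p)]


class _CoxProblem:
    """Sorted data and tie-group bookkeeping for the weighted Breslow likelihood."""

    def __init__(self, X, time, event, w_pre, w_ev):
        n = len(time)
        order = np.argsort(-time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.w_pre = w_pre[order]
        self.w_ev = w_ev[order]
        self.n, self.p = self.X.shape

        ev = np.flatnonzero(self.event)
        if ev.size == 0:
            raise ValueError("no events in the data")
        self.ev_idx = ev
        ev_times = self.time[ev]
        # group boundaries among events (descending times)
        starts = np.flatnonzero(np.r_[True, np.diff(ev_times) != 0])
        self.grp_starts = starts
        self.grp_times = ev_times[starts]            # descending unique event times
        # last index (inclusive) of the risk set for each group
        self.grp_riskend = (
            np.searchsorted(-self.time, -self.grp_times, side="right") - 1
        )
        self.n_groups = len(starts)

    def _group_sum(self, arr):
        """Sum an event-indexed array within tie groups."""
        return np.add.reduceat(arr, self.grp_starts, axis=0)

    def quantities(self, beta, want_hessian=True):
        """Weighted Breslow log-likelihood, score and information at beta."""
        lp = self.X @ beta
        lp_shift = lp - lp.max()
        r = np.exp(lp_shift)
        wpr = self.w_pre * r

        cum0 = np.cumsum(wpr)
        cum1 = np.cumsum(wpr[:, None] * self.X, axis=0)

        ev = self.ev_idx
        Xe = self.X[ev]
        we = self.w_ev[ev]
        diff_r = (self.w_ev[ev] - self.w_pre[ev]) * r[ev]

        m_g = self._group_sum(we)                               # sum of event weights
        num_lp = self._group_sum(we * lp[ev])
        adj0 = self._group_sum(diff_r)
        adj1 = self._group_sum(diff_r[:, None] * Xe)

        e_g = self.grp_riskend
        D = cum0[e_g] + adj0
        S1 = cum1[e_g] + adj1

        loglik = float(np.sum(num_lp) - np.sum(m_g * (np.log(D) + lp.max())))
        xbar = S1 / D[:, None]
        score = self._group_sum(we[:, None] * Xe).sum(axis=0) - (
            m_g[:, None] * xbar
        ).sum(axis=0)

        info = None
        if want_hessian:
            cum2 = np.cumsum(
                wpr[:, None, None] * (self.X[:, :, None] * self.X[:, None, :]),
                axis=0,
            )
            adj2 = self._group_sum(
                diff_r[:, None, None] * (Xe[:, :, None] * Xe[:, None, :])
            )
            S2 = cum2[e_g] + adj2
            info = (
                m_g[:, None, None]
                * (S2 / D[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
            ).sum(axis=0)
        return loglik, score, info, (D, m_g, xbar, r, lp.max())

    def score_residuals(self, beta):
        """Per-subject weighted score residuals (Lin-Wei), for the sandwich."""
        _, _, _, (D, m_g, xbar, r, _) = self.quantities(beta, want_hessian=False)
        A = m_g / D                           # per group
        B = (m_g / D)[:, None] * xbar         # per group, p-vector
        # suffix sums over groups (groups sorted by descending time)
        SA = np.cumsum(A[::-1])[::-1]
        SB = np.cumsum(B[::-1], axis=0)[::-1]
        # first group (smallest index) with tau_g <= t_i
        g_i = np.searchsorted(-self.grp_times, -self.time, side="left")
        SA_i = np.where(g_i < self.n_groups, SA[np.minimum(g_i, self.n_groups - 1)], 0.0)
        SB_i = np.where(
            (g_i < self.n_groups)[:, None],
            SB[np.minimum(g_i, self.n_groups - 1)],
            0.0,
        )
        U = -r[:, None] * self.w_pre[:, None] * (SA_i[:, None] * self.X - SB_i)
        # event subjects: numerator term and own-group weight correction
        ev = self.ev_idx
        grp_of_event = np.repeat(
            np.arange(self.n_groups),
            np.diff(np.r_[self.grp_starts, len(ev)]),
        )
        xc = self.X[ev] - xbar[grp_of_event]
        U[ev] += self.w_ev[ev][:, None] * xc
        U[ev] -= (
            ((self.w_ev[ev] - self.w_pre[ev]) * r[ev] * A[grp_of_event])[:, None] * xc
        )
        return U

    def baseline_cumhaz(self, beta, center):
        """Weighted Breslow baseline cumulative hazard with centered covariates."""
        lp_c = (self.X - center) @ beta
        r = np.exp(lp_c)
        wpr = self.w_pre * r
        cum0 = np.cumsum(wpr)
        ev = self.ev_idx
        diff_r = (self.w_ev[ev] - self.w_pre[ev]) * r[ev]
        m_g = self._group_sum(self.w_ev[ev])
        adj0 = self._group_sum(diff_r)
        D = cum0[self.grp_riskend] + adj0
        inc = m_g / D
        times = self.grp_times[::-1]          # ascending
        H0 = np.cumsum(inc[::-1])
        return times, H0


def fit_cox(
    X,
    outcome: SurvivalOutcome,
    weights: BarlowWeights | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> FittedCox:
    """Maximize the Barlow-weighted Breslow partial likelihood.

    Newton-Raphson with step-halving; convergence when the maximum absolute
    score falls below ``score_tol`` or the relative log-likelihood change
    below ``ll_tol``.  Non-convergence is flagged on the result, never silent.
    """
    if ties != "breslow":
        raise ValueError("only Breslow tie handling is implemented")
    names = _column_names(X, np.shape(X)[1])
    Xm = _as_matrix(X)
    n, p = Xm.shape
    if len(outcome) != n:
        raise ValueError("X and outcome lengths differ")
    if outcome.event.sum() < 1:
        raise ValueError("at least one event is required")
    if weights is None:
        weights = BarlowWeights.unit(n)

    # centering for numerical stability and for the baseline hazard
    w_avg = weights.averaging_weight()
    center = (w_avg @ Xm) / w_avg.sum()
    Xc = Xm - center

    if np.linalg.matrix_rank(Xc, tol=1e-10 * max(1.0, np.abs(Xc).max())) < p:
        raise ValueError("covariate matrix is collinear (rank-deficient)")

    prob = _CoxProblem(Xc, outcome.time, outcome.event, weights.pre_event, weights.at_event)

    beta = np.zeros(p)
    ll, score, info, _ = prob.quantities(beta)
    converged = False
    messages: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix (collinear covariates?)")
        # step-halving: never decrease the weighted partial likelihood
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, score_new, info_new, _ = prob.quantities(cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll_prev, ll, score, info = cand, ll, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > 50.0:
            messages.append(
                "monotone likelihood suspected (|beta| > 50); estimate capped"
            )
            beta = np.clip(beta, -50.0, 50.0)
            warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)
            break
        if np.max(np.abs(score)) <= score_tol or (
            abs(ll - ll_prev) <= ll_tol * max(1.0, abs(ll))
        ):
            converged = True
            break
    if not converged and not messages:
        messages.append(f"Newton-Raphson did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    U = prob.score_residuals(beta)
    meat = U.T @ U
    robust = cov @ meat @ cov
    robust_se = np.sqrt(np.diag(robust))

    times, H0 = prob.baseline_cumhaz(beta, center=np.zeros(p))  # Xc already centered
    return FittedCox(
        names=names,
        beta=beta,
        se=se,
        robust_se=robust_se,
        loglik=ll,
        baseline_times=times,
        baseline_cumhaz=H0,
        center=center,
        converged=converged,
        n_iter=it,
        max_time=float(outcome.time.max()),
        messages=messages,
    )


def predict_absolute_risk(model: FittedCox, X, horizon: float) -> np.ndarray:
    """Absolute event risk by ``horizon``: 1 - exp(-H0(h) * exp(lp)).

    The linear predictor is centered at the fitting-sample weighted covariate
    mean, so a subject at the mean has risk 1 - exp(-H0(h)).
    """
    if horizon > model.max_time + 1e-12:
        raise ValueError(
            f"horizon {horizon} exceeds maximum observed follow-up {model.max_time}"
        )
    lp = model.linear_predictor(X)
    H = model.cumhaz_at(horizon)
    risk = 1.0 - np.exp(-H * np.exp(lp))
    return np.clip(risk, 0.0, 1.0)


def weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    m = np.average(x, weights=w)
    return float(np.sqrt(np.average((x - m) ** 2, weights=w)))


def hazard_ratio_per_sd(
    feature: str,
    data: pd.DataFrame,
    outcome: SurvivalOutcome,
    weights: BarlowWeights,
    adjustment: list | None = None,
    sex: str | None = None,
) -> AssociationResult:
    """Adjusted hazard ratio per one (weighted) SD increment of one feature.

    The feature is standardized by the stratum's weighted SD, entered into a
    single Cox model alongside the adjustment set, and its Wald CI is taken
    from the robust standard error.
    """
    from .synthdata import SCORE2_VARIABLES

    adjustment = SCORE2_VARIABLES if adjustment is None else list(adjustment)
    if feature not in data.columns:
        raise KeyError(f"feature {feature!r} not in data")
    if sex is not None:
        idx = (data["sex"] == sex).to_numpy()
        if not idx.any():
            raise ValueError(f"empty stratum {sex!r}")
        data = data.loc[idx]
        outcome = outcome.subset(idx)
        weights = weights.subset(idx)
    n_events = int(outcome.event.sum())
    if n_events < 10:
        raise ValueError(f"stratum has only {n_events} events (need >= 10)")

    x = data[feature].to_numpy(dtype=float)
    sd = weighted_sd(x, weights.averaging_weight())
    if sd <= 0:
        raise ValueError(f"feature {feature!r} has zero variance in stratum")
    Xfit = data[adjustment].copy()
    Xfit[feature] = (x - x.mean()) / sd
    fit = fit_cox(Xfit, outcome, weights)
    tab = fit.coef_table().loc[feature]
    return AssociationResult(
        feature=feature,
        sex=sex if sex is not None else "all",
        hazard_ratio=float(tab["hr"]),
        ci_low=float(tab["hr_ci_low"]),
        ci_high=float(tab["hr_ci_high"]),
        p_value=float(tab["p"]),
        n_events=n_events,
    )
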