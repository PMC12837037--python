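"""Discrimination, reclassification, calibration and correlation analytics.

Harrell's C-index is computed by exact pair counting with the usual
censoring rules (the earlier time in a comparable pair must be an event;
score ties count 1/2).  Differences between correlated C-indices are tested
with a U-statistic variance estimator for the paired concordance estimators
(the approach of Kang and colleagues): both C's share the comparability
kernel, their joint influence functions are projected per subject, and the
variance of the difference follows by the delta method.

Net reclassification (categorical with fixed absolute-risk cut-points, and
category-free) and the integrated discrimination improvement handle
censoring at the horizon through Kaplan-Meier conditional event-status
weights; with no censoring they reduce exactly to the classical proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthdata import SurvivalOutcome

__all__ = [
    "DiscriminationComparison",
    "ReclassificationResult",
    "CalibrationTable",
    "harrell_c",
    "compare_c",
    "categorical_nri",
    "continuous_nri",
    "idi",
    "incremental_c",
    "calibration_deciles",
    "spearman_matrix",
]

_Z975 = norm.ppf(0.975)


@dataclass
class DiscriminationComparison:
    c_ref: float
    c_ref_ci: tuple
    c_new: float
    c_new_ci: tuple
    delta_c: float
    var_delta: float
    p_value: float


@dataclass
class ReclassificationResult:
    nri_total: float
    nri_events: float
    nri_nonevents: float
    ci_total: tuple | None = None
    ci_events: tuple | None = None
    ci_nonevents: tuple | None = None
    cuts: tuple | None = None

    def __post_init__(self):
        if abs(self.nri_total - (self.nri_events + self.nri_nonevents)) > 1e-9:
            raise ValueError("NRI total must equal events + non-events components")


@dataclass
class CalibrationTable:
    table: pd.DataFrame  # columns: bin, n, mean_predicted, observed


# ---------------------------------------------------------------------------
# concordance


def _concordance_sums(time, event, scores, chunk=512):
    """Per-subject influence sums and pairwise cross-moments for one or more
    score vectors.

    Returns ``(conc_rows, comp_rows, cross)``: ``conc_rows[m, i]`` is the sum
    over j != i of the (symmetric) concordance kernel of score m,
    ``comp_rows[i]`` the comparability kernel sum, and ``cross[(a, b)]`` the
    pairwise sums over ordered pairs of products of kernels (keys ``(m, m')``
    for concordance products and ``(m, "b")`` for concordance-comparability
    products), needed for the second-order U-statistic variance term.  Pair
    (i, j) is comparable when the smaller time carries an event (ties in
    time: event vs censored only); concordance is 1 if the event-bearer has
    the higher score, 1/2 on score ties.
    """
    n = len(time)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k = scores.shape[0]
    conc_rows = np.zeros((k, n))
    comp_rows = np.zeros(n)
    cross = {(a, b): 0.0 for a in range(k) for b in range(a, k)}
    cross.update({(m, "b"): 0.0 for m in range(k)})
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti = t[sl][:, None]
        ei = e[sl][:, None]
        # i is the event-bearer of the pair
        comp_i = ei & ((ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :]))
        # j is the event-bearer
        comp_j = e[None, :] & ((t[None, :] < ti) | ((t[None, :] == ti) & ~ei))
        comp = comp_i | comp_j
        idx = np.arange(sl.start, sl.stop)
        comp[np.arange(sl.stop - sl.start), idx] = False
        comp_rows[sl] += comp.sum(axis=1)
        ccs = []
        for m in range(k):
            si = scores[m][sl][:, None]
            sj = scores[m][None, :]
            winner_i = np.where(comp_i, np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0)), 0.0)
            winner_j = np.where(comp_j, np.where(sj > si, 1.0, np.where(si == sj, 0.5, 0.0)), 0.0)
            cc = winner_i + winner_j
            cc[np.arange(sl.stop - sl.start), idx] = 0.0
            conc_rows[m][sl] += cc.sum(axis=1)
            cross[(m, "b")] += float(cc.sum())  # conc is 0 off the comparable set
            ccs.append(cc)
        for a in range(k):
            for b in range(a, k):
                cross[(a, b)] += float((ccs[a] * ccs[b]).sum())
    return conc_rows, comp_rows, cross


def _c_variance(conc_rows_list, comp_rows, cs, n, second_order):
    """Delta-method variances of C (or a C-difference) as ratio-of-U-statistics.

    For the centered kernel phi_ij = conc_ij - c * comp_ij the estimate uses
    the exact degree-2 U-statistic variance
    ``[4 (n-2) zeta1 + 2 zeta2] / (n (n-1))`` with zeta1 the variance of the
    per-subject Hajek projections and zeta2 the pair-level kernel variance
    (``second_order`` supplies (sum conc^2, sum conc*comp) over ordered
    pairs per target); everything is scaled by the mean comparability.
    """
    Bc = comp_rows.sum()
    Bmean = Bc / (n * (n - 1))
    b_bar = comp_rows / (n - 1)
    out = []
    for rows, c, (s_cc, s_cb) in zip(conc_rows_list, cs, second_order):
        phi_bar = rows / (n - 1) - c * b_bar
        zeta1 = float(np.var(phi_bar, ddof=1)) if n > 1 else 0.0
        zeta2 = (s_cc - 2.0 * c * s_cb + c * c * Bc) / (n * (n - 1))
        var = (4.0 * (n - 2) * zeta1 + 2.0 * zeta2) / (n * (n - 1)) / Bmean**2
        out.append(max(0.0, var))
    return out


def harrell_c(risk, outcome: SurvivalOutcome, with_ci: bool = True):
    """Harrell's concordance index with an asymptotic (U-statistic) 95% CI."""
    risk = np.asarray(risk, dtype=float)
    n = len(risk)
    if len(outcome) != n:
        raise ValueError("risk and outcome lengths differ")
    conc_rows, comp_rows, cross = _concordance_sums(
        outcome.time, outcome.event, risk
    )
    A = conc_rows[0].sum()
    Bc = comp_rows.sum()
    if Bc == 0:
        raise ValueError("no comparable pairs")
    c = A / Bc
    if not with_ci:
        return float(c), (np.nan, np.nan)
    var = _c_variance(
        [conc_rows[0]], comp_rows, [c], n,
        [(cross[(0, 0)], cross[(0, "b")])],
    )[0]
    half = _Z975 * np.sqrt(var)
    return float(c), (float(c - half), float(c + half))


def compare_c(risk_ref, risk_new, outcome: SurvivalOutcome) -> DiscriminationComparison:
    """Test the difference between two correlated C-indices on the same subjects."""
    risk_ref = np.asarray(risk_ref, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    n = len(risk_ref)
    if len(risk_new) != n or len(outcome) != n:
        raise ValueError("both risk vectors must cover the same subjects")
    conc_rows, comp_rows, cross = _concordance_sums(
        outcome.time, outcome.event, np.vstack([risk_ref, risk_new])
    )
    Bc = comp_rows.sum()
    if Bc == 0:
        raise ValueError("no comparable pairs")
    c1 = conc_rows[0].sum() / Bc
    c2 = conc_rows[1].sum() / Bc
    # difference kernel: sum d^2 = S22 + S11 - 2 S12, sum d*comp = S2b - S1b
    var1, var2, var_d = _c_variance(
        [conc_rows[0], conc_rows[1], conc_rows[1] - conc_rows[0]],
        comp_rows,
        [c1, c2, c2 - c1],
        n,
        [
            (cross[(0, 0)], cross[(0, "b")]),
            (cross[(1, 1)], cross[(1, "b")]),
            (cross[(0, 0)] + cross[(1, 1)] - 2.0 * cross[(0, 1)],
             cross[(1, "b")] - cross[(0, "b")]),
        ],
    )
    delta = c2 - c1
    if var_d <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(delta) / np.sqrt(var_d)))
    return DiscriminationComparison(
        c_ref=float(c1),
        c_ref_ci=(float(c1 - _Z975 * np.sqrt(var1)), float(c1 + _Z975 * np.sqrt(var1))),
        c_new=float(c2),
        c_new_ci=(float(c2 - _Z975 * np.sqrt(var2)), float(c2 + _Z975 * np.sqrt(var2))),
        delta_c=float(delta),
        var_delta=var_d,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# reclassification


def _km_survival(time, event):
    """Kaplan-Meier survival curve as step arrays (times, S)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event)
    sf = km.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _event_weights(outcome: SurvivalOutcome, horizon: float) -> np.ndarray:
    """P(event by horizon | observed data) per subject under independent censoring.

    Events by the horizon get 1, subjects followed beyond it get 0, and
    subjects censored at c < horizon get (S(c) - S(h)) / S(c) from the
    overall Kaplan-Meier curve.  With no censoring before the horizon this
    is exactly the observed event indicator.
    """
    t, e = outcome.time, outcome.event.astype(bool)
    w = np.zeros(len(t))
    w[e & (t <= horizon)] = 1.0
    censored = ~e & (t < horizon)
    if censored.any():
        kt, ks = _km_survival(t, e.astype(int))

        def S(x):
            i = np.searchsorted(kt, x, side="right")
            return np.where(i == 0, 1.0, ks[np.maximum(i - 1, 0)])

        Sc = S(t[censored])
        Sh = float(S(np.array([horizon]))[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            w[censored] = np.where(Sc > 0, np.clip((Sc - Sh) / Sc, 0.0, 1.0), 0.0)
    return w


def _check_probs(p, name):
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name} must be probabilities in [0, 1]")
    return p


def _nri_components(up, down, w):
    sw = w.sum()
    swn = (1.0 - w).sum()
    if sw <= 0:
        raise ValueError("no events by the horizon")
    p_up_e = float((w * up).sum() / sw)
    p_dn_e = float((w * down).sum() / sw)
    p_up_ne = float(((1 - w) * up).sum() / swn) if swn > 0 else 0.0
    p_dn_ne = float(((1 - w) * down).sum() / swn) if swn > 0 else 0.0
    ev = p_up_e - p_dn_e
    ne = p_dn_ne - p_up_ne
    return ev, ne


def _bootstrap_ci(stat_fn, outcome, arrays, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = len(outcome)
    stats = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = stat_fn(outcome.subset(idx), *[a[idx] for a in arrays])
        except ValueError:
            stats[b] = np.nan
    lo = np.nanpercentile(stats, 2.5, axis=0)
    hi = np.nanpercentile(stats, 97.5, axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


def categorical_nri(
    p_ref,
    p_new,
    outcome: SurvivalOutcome,
    cuts: tuple = (0.15, 0.30),
    horizon: float = 10.0,
    n_boot: int = 1000,
    seed: int = 0,
    with_ci: bool = True,
) -> ReclassificationResult:
    """Categorical NRI with fixed absolute-risk categories (default 0-15%,
    >15-30%, >30%), censoring handled by KM event-status weights."""
    cuts = tuple(cuts)
    if not all(0.0 < c < 1.0 for c in cuts) or list(cuts) != sorted(set(cuts)):
        raise ValueError("cuts must be strictly increasing within (0, 1)")
    p_ref = _check_probs(p_ref, "p_ref")
    p_new = _check_probs(p_new, "p_new")
    edges = np.r_[0.0, cuts, 1.0 + 1e-12]

    def _stat(out, pr, pn):
        cr = np.digitize(pr, edges) - 1
        cn = np.digitize(pn, edges) - 1
        w = _event_weights(out, horizon)
        ev, ne = _nri_components(cn > cr, cn < cr, w)
        return ev + ne, ev, ne

    tot, ev, ne = _stat(outcome, p_ref, p_new)
    cis = (
        _bootstrap_ci(_stat, outcome, [p_ref, p_new], n_boot, seed)
        if with_ci
        else [None, None, None]
    )
    return ReclassificationResult(
        nri_total=tot, nri_events=ev, nri_nonevents=ne,
        ci_total=cis[0], ci_events=cis[1], ci_nonevents=cis[2], cuts=cuts,
    )


def continuous_nri(
    p_ref, p_new, outcome: SurvivalOutcome, horizon: float = 10.0,
    n_boot: int = 1000, seed: int = 0, with_ci: bool = True,
) -> ReclassificationResult:
    """Category-free NRI(>0): any upward/downward risk change counts."""
    p_ref = _check_probs(p_ref, "p_ref")
    p_new = _check_probs(p_new, "p_new")

    def _stat(out, pr, pn):
        w = _event_weights(out, horizon)
        ev, ne = _nri_components(pn > pr, pn < pr, w)
        return ev + ne, ev, ne

    tot, ev, ne = _stat(outcome, p_ref, p_new)
    cis = (
        _bootstrap_ci(_stat, outcome, [p_ref, p_new], n_boot, seed)
        if with_ci
        else [None, None, None]
    )
    return ReclassificationResult(
        nri_total=tot, nri_events=ev, nri_nonevents=ne,
        ci_total=cis[0], ci_events=cis[1], ci_nonevents=cis[2],
    )


def idi(
    p_ref, p_new, outcome: SurvivalOutcome, horizon: float = 10.0,
    n_boot: int = 1000, seed: int = 0, with_ci: bool = True,
):
    """Integrated discrimination improvement: difference in discrimination
    slope (mean risk in events minus non-events) between the two models."""
    p_ref = _check_probs(p_ref, "p_ref")
    p_new = _check_probs(p_new, "p_new")

    def _stat(out, pr, pn):
        w = _event_weights(out, horizon)
        sw, swn = w.sum(), (1 - w).sum()
        if sw <= 0:
            raise ValueError("no events by the horizon")
        d = pn - pr
        val = float((w * d).sum() / sw) - (
            float(((1 - w) * d).sum() / swn) if swn > 0 else 0.0
        )
        return val, val, val

    val = _stat(outcome, p_ref, p_new)[0]
    if not with_ci:
        return val, (np.nan, np.nan)
    ci = _bootstrap_ci(_stat, outcome, [p_ref, p_new], n_boot, seed)[0]
    return val, ci


# ---------------------------------------------------------------------------
# model-level helpers


def incremental_c(
    feature: str,
    base_spec,
    data: pd.DataFrame,
    outcome: SurvivalOutcome,
    weights,
    sex: str,
    horizon: float = 10.0,
) -> float:
    """C-index gain from adding one biomarker to the base model, per sex."""
    from .riskmodel import fit_single_sex

    if feature in base_spec.base_variables:
        raise ValueError(f"{feature!r} is already a base covariate")
    keep = (data["sex"] == sex).to_numpy()
    d = data.loc[keep].reset_index(drop=True)
    o = outcome.subset(keep)
    w = weights.subset(keep) if weights is not None else None
    base_cols = list(base_spec.base_variables)
    fit0 = fit_single_sex(base_cols, d, o, w)
    fit1 = fit_single_sex(base_cols + [feature], d, o, w)
    from .survcox import predict_absolute_risk

    r0 = predict_absolute_risk(fit0, d[base_cols], horizon)
    r1 = predict_absolute_risk(fit1, d[base_cols + [feature]], horizon)
    c0, _ = harrell_c(r0, o)
    c1, _ = harrell_c(r1, o)
    return float(c1 - c0)


def calibration_deciles(
    p, outcome: SurvivalOutcome, horizon: float = 10.0, n_bins: int = 10
) -> CalibrationTable:
    """Observed (Kaplan-Meier) versus mean predicted risk across risk deciles."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = _check_probs(p, "p")
    # equal-count bins with stable tie handling; identical risks collapse bins
    ranks = pd.Series(p).rank(method="first")
    try:
        bins = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(np.zeros(len(p), dtype=int))
    rows = []
    for b in sorted(bins.unique()):
        m = (bins == b).to_numpy()
        t, e = outcome.time[m], outcome.event[m]
        if e.sum() == 0:
            observed = 0.0
        else:
            kt, ks = _km_survival(t, e)
            i = np.searchsorted(kt, horizon, side="right")
            observed = 1.0 - (1.0 if i == 0 else float(ks[i - 1]))
        rows.append(
            {
                "bin": int(b),
                "n": int(m.sum()),
                "mean_predicted": float(p[m].mean()),
                "observed": observed,
            }
        )
    return CalibrationTable(pd.DataFrame(rows))


def spearman_matrix(
    features: list, data: pd.DataFrame, sex: str | None = None
) -> pd.DataFrame:
    """Pairwise Spearman correlations on complete pairs, per sex stratum."""
    if len(features) < 2:
        raise ValueError("need at least two features")
    d = data
    if sex is not None:
        d = data.loc[data["sex"] == sex]
    return d[list(features)].corr(method="spearman")
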