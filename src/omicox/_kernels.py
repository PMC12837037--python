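"""Compiled inner loops for the penalized weighted Cox path solver.

The path solver follows the glmnet recipe: iteratively reweighted least
squares around the current linear predictor (diagonal Hessian approximation
of the weighted Breslow partial likelihood) with cyclic coordinate descent
and soft-thresholding on the working least-squares problem, warm starts along
a decreasing lambda grid, active-set iteration, and a full KKT sweep at
convergence of every lambda.  Barlow case-cohort weights (pre-event /
at-event) are carried through the risk-set sums exactly as in the Newton
solver of :mod:`omicox.survcox`.

Data layout: rows sorted by *descending* follow-up time.  ``ev_idx`` indexes
event rows (in sorted order), tie groups of equal event times are delimited
by ``grp_starts`` (into ``ev_idx``); ``grp_riskend[g]`` is the last sorted
row index belonging to the risk set of group ``g``; ``g_ptr[i]`` is the first
group whose event time is <= the row's time (``n_groups`` when none).
"""

import numpy as np
from numba import njit

_NOPYTHON = dict(cache=True, fastmath=True)


@njit(**_NOPYTHON)
def eta_quantities(eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr):
    """Log-likelihood, per-row gradient and diagonal Hessian wrt eta."""
    n = eta.shape[0]
    G = grp_starts.shape[0]
    nev = ev_idx.shape[0]
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - shift)

    cum0 = np.empty(n)
    s = 0.0
    for i in range(n):
        s += w_pre[i] * r[i]
        cum0[i] = s

    D = np.empty(G)
    m = np.empty(G)
    ll = 0.0
    for gi in range(G):
        e0 = grp_starts[gi]
        e1 = grp_starts[gi + 1] if gi + 1 < G else nev
        adj = 0.0
        mg = 0.0
        for k in range(e0, e1):
            i = ev_idx[k]
            adj += (w_ev[i] - w_pre[i]) * r[i]
            mg += w_ev[i]
            ll += w_ev[i] * eta[i]
        D[gi] = cum0[grp_riskend[gi]] + adj
        m[gi] = mg
        ll -= mg * (np.log(D[gi]) + shift)

    S1 = np.zeros(G + 1)
    S2 = np.zeros(G + 1)
    for gi in range(G - 1, -1, -1):
        S1[gi] = S1[gi + 1] + m[gi] / D[gi]
        S2[gi] = S2[gi + 1] + m[gi] / (D[gi] * D[gi])

    g = np.empty(n)
    h = np.empty(n)
    for i in range(n):
        a = w_pre[i] * r[i]
        gp = g_ptr[i]
        g[i] = -a * S1[gp]
        h[i] = a * S1[gp] - a * a * S2[gp]
    for gi in range(G):
        e0 = grp_starts[gi]
        e1 = grp_starts[gi + 1] if gi + 1 < G else nev
        mD = m[gi] / D[gi]
        mD2 = m[gi] / (D[gi] * D[gi])
        for k in range(e0, e1):
            i = ev_idx[k]
            a = w_pre[i] * r[i]
            b = w_ev[i] * r[i]
            g[i] += w_ev[i] - (b - a) * mD
            h[i] += (b - a) * mD - (b * b - a * a) * mD2
    return ll, g, h


@njit(**_NOPYTHON)
def lasso_path(
    X,
    w_pre,
    w_ev,
    ev_idx,
    grp_starts,
    grp_riskend,
    g_ptr,
    lambdas,
    pf,
    beta0,
    maxit_irls,
    maxit_cd,
    tol_cd,
    tol_kkt,
    dfmax,
):
    """Coordinate-descent path over a decreasing lambda grid.

    Returns (B, LL, n_done) with B[l] the coefficient vector (standardized
    scale) and LL[l] the weighted Breslow log-likelihood at grid point l.
    The penalized objective is -loglik/n + lam * sum(pf * |beta|).  Each
    lambda is iterated until the true KKT conditions hold to ``tol_kkt``.
    The path stops early (n_done < len(lambdas)) once the active penalized
    set exceeds ``dfmax`` (pass a value > p to disable).
    """
    n, p = X.shape
    L = lambdas.shape[0]
    W = float(n)
    beta = beta0.copy()
    eta = np.dot(X, beta)
    B = np.zeros((L, p))
    LL = np.zeros(L)
    active = np.zeros(p, np.bool_)
    for j in range(p):
        if pf[j] == 0.0 or beta[j] != 0.0:
            active[j] = True
    dj = np.zeros(p)
    gh0 = np.empty(n)
    n_done = L

    for l in range(L):
        lam = lambdas[l]
        certified = False
        for _outer in range(maxit_irls):
            ll, g, h = eta_quantities(
                eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr
            )
            for i in range(n):
                if h[i] < 1e-10:
                    h[i] = 1e-10
                gh0[i] = g[i] / h[i]
            res = gh0.copy()  # z - X beta at the current beta
            for j in range(p):
                if active[j]:
                    col = X[:, j]
                    s = 0.0
                    for i in range(n):
                        s += h[i] * col[i] * col[i]
                    dj[j] = s / W

            beta_old_max_change = 0.0
            for _sweep in range(maxit_cd):
                maxdelta = 0.0
                for j in range(p):
                    if not active[j]:
                        continue
                    bj = beta[j]
                    col = X[:, j]
                    s = 0.0
                    for i in range(n):
                        s += h[i] * col[i] * res[i]
                    num = s / W + dj[j] * bj
                    if pf[j] == 0.0:
                        bnew = num / dj[j]
                    else:
                        anum = abs(num) - lam * pf[j]
                        if anum > 0.0:
                            bnew = anum / dj[j] if num > 0 else -anum / dj[j]
                        else:
                            bnew = 0.0
                    if bnew != bj:
                        d = bnew - bj
                        for i in range(n):
                            res[i] -= col[i] * d
                        beta[j] = bnew
                        ch = dj[j] * d * d
                        if ch > maxdelta:
                            maxdelta = ch
                if maxdelta < tol_cd:
                    break
                if maxdelta > beta_old_max_change:
                    beta_old_max_change = maxdelta
            # eta <- X beta, reconstructed from the maintained residual
            for i in range(n):
                eta[i] = eta[i] + gh0[i] - res[i]

            if beta_old_max_change < tol_cd * 10.0:
                # quadratic model converged; certify true KKT on the full set
                ll2, g2, _h2 = eta_quantities(
                    eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr
                )
                grad = np.dot(g2, X) / W  # gradient of +loglik/n
                viol = 0.0
                for j in range(p):
                    if pf[j] == 0.0:
                        v = abs(grad[j])
                    elif beta[j] != 0.0:
                        sgn = 1.0 if beta[j] > 0 else -1.0
                        v = abs(grad[j] - lam * pf[j] * sgn)
                    else:
                        v = abs(grad[j]) - lam * pf[j]
                        if v > tol_kkt and not active[j]:
                            active[j] = True
                    if v > viol:
                        viol = v
                if viol <= tol_kkt:
                    LL[l] = ll2
                    certified = True
                    break
        if not certified:
            LL[l] = eta_quantities(
                eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr
            )[0]
        for j in range(p):
            B[l, j] = beta[j]
        nact = 0
        for j in range(p):
            if pf[j] > 0.0 and beta[j] != 0.0:
                nact += 1
        if nact > dfmax:
            n_done = l + 1
            break
    return B, LL, n_done


@njit(**_NOPYTHON)
def loglik_at(eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr):
    ll, _g, _h = eta_quantities(
        eta, w_pre, w_ev, ev_idx, grp_starts, grp_riskend, g_ptr
    )
    return ll
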