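"""Compiled threshold-scan kernel for the split search.

Scoring one candidate split requires, in each daughter: recomputing the
Kaplan-Meier weights, refitting the weighted node model, re-imputing the
censored residuals and summing their squares. This module JIT-compiles that
inner loop (numba) over all candidate thresholds of one numeric covariate at
once. The pure-Python path in :mod:`prismsurv.tree` remains the readable
reference and the fallback when numba is unavailable; the two agree to
floating-point round-off.

Algebraic note: with a 0/1 focus variable the weighted normal equations of
the (1, x, x*w) design reduce by row elimination to

    theta0 = (b0 - bu) / (s0 - su)
    [su  sv ] [theta1]   [bu - su*theta0]
    [sv  svv] [theta2] = [bv - sv*theta0]

with s* / b* the weighted design sums, so no general solver is needed.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _side_sse(ys, ds, xs, ws, m, use_w, wt, resid, uncens):
    """Imputed-residual SSE of the refit on one daughter.

    The daughter's (y, delta, x, w) occupy the first ``m`` slots of the
    buffers, already in y-ascending / events-first order. ``wt``, ``resid``
    and ``uncens`` are scratch buffers of length >= m. Returns -1.0 for a
    degenerate fit.
    """
    s0 = 0.0
    su = 0.0
    sv = 0.0
    svv = 0.0
    b0 = 0.0
    bu = 0.0
    bv = 0.0
    prod = 1.0
    for k in range(m):
        dk = (ds[k] / (m - k)) * prod
        if ds[k] > 0 and m - k - 1 > 0:
            prod *= (m - k - 1.0) / (m - k)
        wt[k] = dk
        yk = ys[k]
        s0 += dk
        b0 += dk * yk
        if xs[k] > 0:
            su += dk
            bu += dk * yk
            if use_w:
                wv = ws[k]
                dv = dk * wv
                sv += dv
                svv += dv * wv
                bv += dv * yk
    if s0 <= 0.0 or su <= 0.0 or s0 - su <= 0.0:
        return -1.0
    t0 = (b0 - bu) / (s0 - su)
    t1 = 0.0
    t2 = 0.0
    use3 = False
    if use_w:
        varw = svv - sv * sv / su
        lim = abs(svv)
        if lim < 1.0:
            lim = 1.0
        if varw > 1e-12 * lim:
            det = su * svv - sv * sv
            r1 = bu - su * t0
            r2 = bv - sv * t0
            t1 = (r1 * svv - sv * r2) / det
            t2 = (su * r2 - sv * r1) / det
            use3 = True
    if not use3:
        t1 = bu / su - t0
    # residuals and censored-residual imputation
    mu = 0
    for k in range(m):
        pred = t0 + t1 * xs[k]
        if use3:
            pred += t2 * xs[k] * ws[k]
        r = ys[k] - pred
        resid[k] = r
        if ds[k] > 0:
            uncens[mu] = r
            mu += 1
    ub = np.sort(uncens[:mu])
    # suffix means of the sorted uncensored residuals
    sm = np.empty(mu)
    acc = 0.0
    for j in range(mu - 1, -1, -1):
        acc += ub[j]
        sm[j] = acc / (mu - j)
    sse = 0.0
    for k in range(m):
        r = resid[k]
        if ds[k] == 0:
            # first index with ub[idx] > r (binary search, side='right')
            lo = 0
            hi = mu
            while lo < hi:
                mid = (lo + hi) // 2
                if ub[mid] <= r:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < mu:
                r = sm[lo]
        sse += r * r
    return sse


@njit(cache=False)
def scan_thresholds(y, delta, x, w, tract, zv, thresholds, min_node,
                    min_epg, hprism, use_w):
    """Daughter SSE sums for every candidate threshold on one covariate.

    All record arrays are sorted by (y ascending, events first). Returns an
    array aligned with ``thresholds``: sum of the two daughters'
    imputed-residual SSEs, or +inf where the candidate is infeasible
    (exclusion criteria or a degenerate daughter fit).
    """
    n = y.size
    nc = thresholds.size
    out = np.full(nc, np.inf)
    yl = np.empty(n)
    dl = np.empty(n, delta.dtype)
    xl = np.empty(n)
    wl = np.empty(n)
    yr = np.empty(n)
    dr = np.empty(n, delta.dtype)
    xr = np.empty(n)
    wr = np.empty(n)
    wt = np.empty(n)
    resid = np.empty(n)
    uncens = np.empty(n)
    for c in range(nc):
        thr = thresholds[c]
        # feasibility: daughter sizes, events per focus group per daughter,
        # and (HPRISM) >= 2 distinct tracts among those events
        nl = 0
        ev = np.zeros((2, 2), np.int64)
        first = np.full((2, 2), -1, np.int64)
        div = np.zeros((2, 2), np.int64)
        for i in range(n):
            side = 0 if zv[i] < thr else 1
            if side == 0:
                nl += 1
            if delta[i] > 0:
                g = 1 if x[i] > 0 else 0
                ev[side, g] += 1
                t = tract[i]
                if first[side, g] < 0:
                    first[side, g] = t
                elif t != first[side, g]:
                    div[side, g] = 1
        if nl < min_node or n - nl < min_node:
            continue
        ok = True
        for side in range(2):
            for g in range(2):
                if ev[side, g] < min_epg:
                    ok = False
                if hprism and div[side, g] == 0:
                    ok = False
        if not ok:
            continue
        # order-preserving partition keeps each side y-sorted
        ml = 0
        mr = 0
        for i in range(n):
            if zv[i] < thr:
                yl[ml] = y[i]
                dl[ml] = delta[i]
                xl[ml] = x[i]
                wl[ml] = w[i]
                ml += 1
            else:
                yr[mr] = y[i]
                dr[mr] = delta[i]
                xr[mr] = x[i]
                wr[mr] = w[i]
                mr += 1
        sl = _side_sse(yl, dl, xl, wl, ml, use_w, wt, resid, uncens)
        if sl < 0.0:
            continue
        sr = _side_sse(yr, dr, xr, wr, mr, use_w, wt, resid, uncens)
        if sr < 0.0:
            continue
        out[c] = sl + sr
    return out
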