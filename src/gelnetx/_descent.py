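"""JIT-compiled cyclic coordinate descent kernels.

The penalty matrix is passed in CSR form (indptr/indices/data plus a
separate diagonal) so that sparse network Laplacians cost O(degree) per
coordinate; dense penalties are converted to CSR by the caller and produce
identical results.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _soft(v, gamma):
    if v > gamma:
        return v - gamma
    if v < -gamma:
        return v + gamma
    return 0.0


@njit(cache=True)
def _objective(r, a, w, lam1, lam2, d, Pp, Pi, Px, n):
    sse = 0.0
    for i in range(r.shape[0]):
        sse += a[i] * r[i] * r[i]
    l1 = 0.0
    for k in range(w.shape[0]):
        l1 += d[k] * abs(w[k])
    quad = 0.0
    for k in range(w.shape[0]):
        if w[k] != 0.0:
            acc = 0.0
            for idx in range(Pp[k], Pp[k + 1]):
                acc += Px[idx] * w[Pi[idx]]
            quad += w[k] * acc
    return 0.5 * sse / n + lam1 * l1 + 0.5 * lam2 * quad


@njit(cache=True)
def _kkt_residual(XT, r, a, w, b, lam1, lam2, d, Pp, Pi, Px, asum, n):
    """Max violation of the subgradient optimality conditions."""
    p = w.shape[0]
    worst = 0.0
    for k in range(p):
        dot = 0.0
        for i in range(r.shape[0]):
            dot += a[i] * XT[k, i] * r[i]
        dot /= n
        pk = 0.0
        for idx in range(Pp[k], Pp[k + 1]):
            pk += Px[idx] * w[Pi[idx]]
        g = -dot + lam2 * pk  # gradient of the smooth part
        if w[k] > 0.0:
            v = abs(g + lam1 * d[k])
        elif w[k] < 0.0:
            v = abs(g - lam1 * d[k])
        else:
            v = abs(g) - lam1 * d[k]
            if v < 0.0:
                v = 0.0
        if v > worst:
            worst = v
    # bias stationarity
    rs = 0.0
    for i in range(r.shape[0]):
        rs += a[i] * r[i]
    v = abs(rs) / asum
    if v > worst:
        worst = v
    return worst


@njit(cache=True)
def cd_fit(XT, y, a, lam1, lam2, d, Pp, Pi, Px, Pdiag,
           w, b_init, tol, max_iter, rel_tol, skip_zero):
    """Cyclic coordinate descent on the weighted squared-error objective.

    Returns (b, n_iter, trace, converged, kkt).  ``skip_zero=False``
    disables the snapped-to-zero caching shortcut: the (zero-delta)
    residual update is then applied for every coordinate, which performs
    the same floating-point operations on the same values, so both paths
    return identical weights.
    """
    p, n = XT.shape
    asum = 0.0
    for i in range(n):
        asum += a[i]
    b = b_init
    # residuals r_i = y_i - w'x_i - b
    r = np.empty(n)
    for i in range(n):
        acc = y[i] - b
        for k in range(p):
            if w[k] != 0.0:
                acc -= w[k] * XT[k, i]
        r[i] = acc
    # per-coordinate curvature s_k = (1/n) sum_i a_i x_ik^2
    s = np.empty(p)
    for k in range(p):
        acc = 0.0
        for i in range(n):
            acc += a[i] * XT[k, i] * XT[k, i]
        s[k] = acc / n
    denom = s + lam2 * Pdiag

    trace = np.empty(max_iter)
    n_iter = 0
    converged = False
    kkt = np.inf
    prev_obj = np.inf
    for it in range(max_iter):
        for k in range(p):
            if denom[k] <= 0.0:
                if w[k] != 0.0:  # frozen at zero
                    for i in range(n):
                        r[i] += w[k] * XT[k, i]
                    w[k] = 0.0
                continue
            dot = 0.0
            for i in range(n):
                dot += a[i] * XT[k, i] * r[i]
            dot /= n
            pk = 0.0
            for idx in range(Pp[k], Pp[k + 1]):
                j = Pi[idx]
                if j != k:
                    pk += Px[idx] * w[j]
            num = dot + w[k] * s[k] - lam2 * pk
            wk = _soft(num, lam1 * d[k]) / denom[k]
            delta = wk - w[k]
            if delta != 0.0 or not skip_zero:
                for i in range(n):
                    r[i] -= delta * XT[k, i]
                w[k] = wk
        # bias: weighted average of residuals
        rs = 0.0
        for i in range(n):
            rs += a[i] * r[i]
        db = rs / asum
        b += db
        for i in range(n):
            r[i] -= db
        obj = _objective(r, a, w, lam1, lam2, d, Pp, Pi, Px, n)
        trace[it] = obj
        n_iter = it + 1
        if it > 0:
            diff = prev_obj - obj
            if diff < 0.0:
                diff = -diff
            scale = 1.0
            if rel_tol:
                scale = max(1.0, abs(prev_obj))
            if diff < tol * scale:
                kkt = _kkt_residual(XT, r, a, w, b, lam1, lam2, d,
                                    Pp, Pi, Px, asum, n)
                if kkt <= 10.0 * tol * scale:
                    converged = True
                    break
        prev_obj = obj
    if not converged:
        kkt = _kkt_residual(XT, r, a, w, b, lam1, lam2, d,
                            Pp, Pi, Px, asum, n)
    return b, n_iter, trace[:n_iter], converged, kkt


@njit(cache=True)
def cd_linear(g, lam1, lam2, d, Pp, Pi, Px, Pdiag, w, tol, max_iter):
    """Coordinate descent for  min_w  -g'w + lam1*sum d|w| + lam2/2 w'Pw.

    This is the inner subproblem of the penalized-PCA iteration.  Requires
    lam2 * P_kk > 0 on coordinates that are to move; others stay at zero.
    Returns (n_iter, converged).
    """
    p = g.shape[0]
    converged = False
    n_iter = 0
    for it in range(max_iter):
        max_delta = 0.0
        for k in range(p):
            dk = lam2 * Pdiag[k]
            if dk <= 0.0:
                if w[k] != 0.0:
                    w[k] = 0.0
                continue
            pk = 0.0
            for idx in range(Pp[k], Pp[k + 1]):
                j = Pi[idx]
                if j != k:
                    pk += Px[idx] * w[j]
            wk = _soft(g[k] - lam2 * pk, lam1 * d[k]) / dk
            delta = abs(wk - w[k])
            if delta > max_delta:
                max_delta = delta
            w[k] = wk
        n_iter = it + 1
        if max_delta < tol:
            converged = True
            break
    return n_iter, converged
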