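"""Independent oracles used by the tests.

These never call the package's coordinate-descent code path: the penalized
objectives are re-minimized through a smooth bound-constrained
reformulation (w = w+ - w-) with scipy's L-BFGS-B, and small quadratic
cases are solved in closed form.
"""

import numpy as np
from scipy.optimize import minimize


def gelnet_objective_loops(X, y, a, w, b, lam1, lam2, d, P):
    """Term-by-term naive evaluation of the penalized objective."""
    n, p = X.shape
    sse = 0.0
    for i in range(n):
        r = y[i] - b
        for j in range(p):
            r -= w[j] * X[i, j]
        sse += a[i] * r * r
    l1 = sum(d[j] * abs(w[j]) for j in range(p))
    quad = 0.0
    for j in range(p):
        for k in range(p):
            quad += w[j] * P[j, k] * w[k]
    return 0.5 * sse / n + lam1 * l1 + 0.5 * lam2 * quad


def convex_regression_oracle(X, y, a, lam1, lam2, d, P):
    """Global minimizer of the penalized weighted least squares problem
    via positive/negative splitting and L-BFGS-B."""
    n, p = X.shape

    def f(z):
        w = z[:p] - z[p:2 * p]
        r = y - X @ w - z[2 * p]
        return (0.5 * (a * r ** 2).sum() / n
                + lam1 * (d * (z[:p] + z[p:2 * p])).sum()
                + 0.5 * lam2 * w @ (P @ w))

    res = minimize(f, np.zeros(2 * p + 1), method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p) + [(None, None)],
                   options=dict(maxiter=20000, ftol=1e-15, gtol=1e-12))
    return res.x[:p] - res.x[p:2 * p], res.x[2 * p]


def convex_logistic_oracle(X, y, lam1, lam2, d, P):
    """Global minimizer of the penalized average negative log-likelihood."""
    n, p = X.shape

    def f(z):
        w = z[:p] - z[p:2 * p]
        eta = X @ w + z[2 * p]
        nll = np.logaddexp(0.0, eta) - y * eta
        return (nll.sum() / n
                + lam1 * (d * (z[:p] + z[p:2 * p])).sum()
                + 0.5 * lam2 * w @ (P @ w))

    res = minimize(f, np.zeros(2 * p + 1), method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p) + [(None, None)],
                   options=dict(maxiter=20000, ftol=1e-15, gtol=1e-12))
    return res.x[:p] - res.x[p:2 * p], res.x[2 * p]


def weighted_least_squares(X, y, a):
    """Closed-form weighted least squares with intercept."""
    n = len(y)
    Xa = np.column_stack([X, np.ones(n)])
    beta = np.linalg.solve(Xa.T * a @ Xa, Xa.T @ (a * y))
    return beta[:-1], beta[-1]
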