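"""Reductions of other losses to the weighted squared-error solver.

Binary logistic regression is handled by iteratively reweighted least
squares: at each outer step the log-likelihood is replaced by its local
quadratic approximation, which is exactly a weighted regression problem
with working responses ``z_i = eta_i + (y_i - p_i) / (p_i (1 - p_i))`` and
sample weights ``a_i = p_i (1 - p_i)``, and the regression subproblem is
solved by the penalized coordinate-descent solver with a warm start.

Network-regularized principal components follow the
linearize/solve/normalize scheme for penalized ratios of quadratic forms:
iterate ``g = (X'X/n) v``, solve the convex surrogate
``min_w -g'w + lambda1 sum d|w| + (lambda2/2) w'Pw`` in closed form per
coordinate, and renormalize to unit length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._descent import cd_linear
from .solver import (FitControl, GELnet, GELnetResults, PenaltyConfig,
                     _as_penalty_csr, _check_xy)

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFitControl", "GELnetLogit", "GELnetLogitResults",
    "GELnetPCA", "ComponentResults",
    "fit_logistic", "fit_pca_component", "deflate",
]


@dataclass
class LogisticFitControl:
    """Outer-loop control for the logistic reduction.

    ``prob_clip`` bounds the IRLS sample weights ``p(1-p)`` away from zero
    so the coordinate-update denominators stay positive.
    """
    outer_tol: float = 1e-5
    outer_max_iter: int = 25
    prob_clip: float = 1e-5

    def __post_init__(self):
        if min(self.outer_tol, self.outer_max_iter, self.prob_clip) <= 0:
            raise ValueError("all control parameters must be positive")


class GELnetLogit:
    """Network-regularized binary logistic regression.

    ``endog`` must contain both classes, coded 0/1.
    """

    def __init__(self, endog, exog, weights=None, d=None, P=None,
                 feature_names=None) -> None:
        X, y, a = _check_xy(exog, endog, weights)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary (0/1)")
        if y.min() == y.max():
            raise ValueError("endog contains a single class")
        self.exog, self.endog, self.base_weights = X, y, a
        self.nobs, self.n_features = X.shape
        self.d, self.P, self._names = d, P, feature_names

    def _nll(self, eta, pen, w):
        """Penalized average negative log-likelihood."""
        a = self.base_weights
        ll = a * (self.endog * eta - np.logaddexp(0.0, eta))
        reg = pen.lambda1 * ((pen.d if pen.d is not None else 1.0)
                             * np.abs(w)).sum()
        C, _ = _as_penalty_csr(pen.P, self.n_features)
        reg += 0.5 * pen.lambda2 * (w @ (C @ w))
        return -ll.sum() / self.nobs + reg

    def fit(self, lambda1: float = 0.0, lambda2: float = 0.0,
            control: Optional[LogisticFitControl] = None,
            inner: Optional[FitControl] = None) -> "GELnetLogitResults":
        ctl = control or LogisticFitControl()
        inner = inner or FitControl()
        X, y = self.exog, self.endog
        pen = PenaltyConfig(lambda1, lambda2, self.d, self.P)
        w = np.zeros(self.n_features)
        ybar = float(self.base_weights @ y / self.base_weights.sum())
        b = float(np.log(ybar / (1.0 - ybar)))
        trace = []
        converged = False
        n_bad = 0
        res = None
        for it in range(ctl.outer_max_iter):
            eta = X @ w + b
            prob = 1.0 / (1.0 + np.exp(-eta))
            v = np.maximum(prob * (1.0 - prob), ctl.prob_clip)
            a = self.base_weights * v
            z = eta + (y - prob) / v
            model = GELnet(z, X, weights=a, d=self.d, P=self.P,
                           feature_names=self._names)
            res = model.fit(lambda1, lambda2, tol=inner.tol,
                            max_iter=inner.max_iter, rel_tol=inner.rel_tol,
                            w_init=w, b_init=b)
            w, b = res.w, res.intercept
            nll = self._nll(X @ w + b, pen, w)
            trace.append(nll)
            if len(trace) > 1:
                diff = trace[-2] - trace[-1]
                if diff < -1e-8:
                    n_bad += 1
                    if n_bad >= 3:
                        logger.warning("logistic outer loop diverging; "
                                       "flagged not converged")
                        break
                else:
                    n_bad = 0
                if abs(diff) < ctl.outer_tol:
                    converged = True
                    break
        return GELnetLogitResults(self, w, b, np.array(trace), converged,
                                  lambda1, lambda2, res)


class GELnetLogitResults:
    """Fitted penalized logistic model."""

    def __init__(self, model, w, b, nll_trace, converged,
                 lambda1, lambda2, last_inner: GELnetResults) -> None:
        import pandas as pd
        names = (last_inner.params.index if last_inner is not None
                 else [f"x{j}" for j in range(len(w))])
        self.model = model
        self.params = pd.Series(w, index=names, name="weight")
        self.intercept = float(b)
        self.nll_trace = nll_trace
        self.converged = converged
        self.lambda1, self.lambda2 = lambda1, lambda2

    @property
    def w(self) -> np.ndarray:
        return self.params.to_numpy()

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.w))

    def predict_linear(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return X @ self.w + self.intercept

    def predict_proba(self, exog=None) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_linear(exog)))

    def summary(self) -> str:
        return (
            "GELnet Logistic Regression Results\n"
            + "=" * 46 + "\n"
            f"samples: {self.model.nobs}  features: {self.model.n_features}"
            f"  nonzero: {self.nnz}\n"
            f"lambda1: {self.lambda1:.6g}  lambda2: {self.lambda2:.6g}\n"
            f"outer iterations: {len(self.nll_trace)}  "
            f"converged: {self.converged}\n"
            f"final penalized NLL: {self.nll_trace[-1]:.6g}"
        )


# ----------------------------------------------------------------------
class GELnetPCA:
    """Sparse network-regularized principal components.

    Seeks a unit vector maximizing the explained variance
    ``v' (X'X/n) v`` subject to the generalized elastic net penalty.
    Requires ``lambda2 > 0`` with a strictly positive penalty diagonal on
    coordinates allowed to be active (the identity default satisfies this).
    """

    def __init__(self, exog, d=None, P=None, feature_names=None) -> None:
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise ValueError("exog must be a finite 2-D array")
        mu = X.mean(axis=0)
        if np.abs(mu).max() > 1e-8 * max(1.0, np.abs(X).max()):
            logger.info("centering columns of exog (max |mean| %.3g)",
                        np.abs(mu).max())
        self.exog = X - mu
        self.nobs, self.n_features = X.shape
        p = self.n_features
        self.d = np.ones(p) if d is None else np.asarray(d, float).ravel()
        self._P_csr, self._P_diag = _as_penalty_csr(P, p)
        self.feature_names = (list(feature_names) if feature_names
                              is not None else [f"x{j}" for j in range(p)])

    def _cov_mult(self, v):
        return self.exog.T @ (self.exog @ v) / self.nobs

    def fit(self, lambda1: float = 0.0, lambda2: float = 1e-8,
            tol: float = 1e-5, max_iter: int = 100,
            v_init=None) -> "ComponentResults":
        p = self.n_features
        if not np.any(self.exog):
            logger.warning("zero data matrix: returning zero component")
            return ComponentResults(self, np.zeros(p), np.array([0.0]),
                                    True, lambda1, lambda2)
        if v_init is None:
            # deterministic start: normalized column norms of X
            v = np.linalg.norm(self.exog, axis=0)
            v /= np.linalg.norm(v)
        else:
            v = np.asarray(v_init, float).ravel().copy()
            v /= max(np.linalg.norm(v), 1e-300)
        C = self._P_csr
        w = v.copy()
        trace = []
        converged = False
        for it in range(max_iter):
            g = self._cov_mult(v)
            cd_linear(g, float(lambda1), float(lambda2), self.d,
                      C.indptr, C.indices, C.data, self._P_diag,
                      w, min(tol, 1e-8) * 1e-2, 1000)
            norm = np.linalg.norm(w)
            if norm == 0.0:
                return ComponentResults(self, np.zeros(p),
                                        np.array(trace + [0.0]), True,
                                        lambda1, lambda2)
            v_new = w / norm
            trace.append(self._surrogate(v_new, lambda1, lambda2))
            if np.abs(v_new - v).max() < tol:
                v = v_new
                converged = True
                break
            v = v_new
        # sign convention: largest-magnitude loading positive
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        return ComponentResults(self, v, np.array(trace), converged,
                                lambda1, lambda2)

    def _surrogate(self, v, lambda1, lambda2):
        return (float(v @ self._cov_mult(v))
                - lambda1 * float((self.d * np.abs(v)).sum())
                - 0.5 * lambda2 * float(v @ (self._P_csr @ v)))


class ComponentResults:
    """A fitted penalized principal component (unit-norm loadings or the
    zero vector when the penalty kills every coordinate)."""

    def __init__(self, model, v, objective_trace, converged,
                 lambda1, lambda2) -> None:
        import pandas as pd
        self.model = model
        self.loadings = pd.Series(v, index=model.feature_names,
                                  name="loading")
        self.objective_trace = objective_trace
        self.converged = converged
        self.lambda1, self.lambda2 = lambda1, lambda2

    @property
    def v(self) -> np.ndarray:
        return self.loadings.to_numpy()

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.v))

    @property
    def explained_variance(self) -> float:
        """``v' (X'X/n) v`` for the fitted loadings."""
        return float(self.v @ self.model._cov_mult(self.v))

    def scores(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return X @ self.v

    def summary(self) -> str:
        return (
            "GELnet Principal Component\n" + "=" * 40 + "\n"
            f"features: {self.model.n_features}  nonzero loadings: "
            f"{self.nnz}\n"
            f"lambda1: {self.lambda1:.6g}  lambda2: {self.lambda2:.6g}\n"
            f"explained variance: {self.explained_variance:.6g}  "
            f"converged: {self.converged}"
        )


def deflate(X, v) -> np.ndarray:
    """Remove the data-space direction ``v`` from ``X``:
    ``X - (X v) v'``.  ``v`` must have unit norm."""
    X = np.asarray(X, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("v must have unit Euclidean norm")
    return X - np.outer(X @ v, v)


# ----------------------------------------------------------------------
def fit_logistic(X, y, pen: Optional[PenaltyConfig] = None,
                 ctl: Optional[LogisticFitControl] = None,
                 sample_weight=None) -> GELnetLogitResults:
    """Functional front-end for :class:`GELnetLogit`."""
    pen = pen or PenaltyConfig()
    model = GELnetLogit(y, X, weights=sample_weight, d=pen.d, P=pen.P)
    return model.fit(pen.lambda1, pen.lambda2, control=ctl)


def fit_pca_component(X, pen: Optional[PenaltyConfig] = None,
                      ctl: Optional[FitControl] = None) -> ComponentResults:
    """Functional front-end for :class:`GELnetPCA` (single component)."""
    pen = pen or PenaltyConfig(lambda2=1e-8)
    ctl = ctl or FitControl()
    model = GELnetPCA(X, d=pen.d, P=pen.P)
    return model.fit(pen.lambda1, pen.lambda2, tol=ctl.tol,
                     max_iter=ctl.max_iter)
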