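"""Multinomial logistic regression by Newton's method.

Small, self-contained fitter for softmax-linear models with a reference
category, used for the year-trend analysis of ordinal score categories when
the proportional-odds assumption does not hold.  Standard errors come from
the inverse observed information; complete separation is detected and the
model is refitted with a small ridge penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MultinomialFit", "fit_multinomial"]


@dataclass
class MultinomialFit:
    """Fitted softmax-linear model; category 0 is the reference."""

    coef: np.ndarray        # (K-1, p)
    se: np.ndarray          # (K-1, p)
    loglik: float
    n_iter: int
    converged: bool
    ridge: float
    separation: bool
    categories: np.ndarray

    @property
    def n_params(self) -> int:
        return self.coef.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Category probabilities (rows sum to 1)."""
        X = np.atleast_2d(np.asarray(X, float))
        eta = np.hstack([np.zeros((X.shape[0], 1)), X @ self.coef.T])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def _loglik_grad_hess(B: np.ndarray, X: np.ndarray, Y: np.ndarray,
                      ridge: float):
    m, p = X.shape
    km1 = B.shape[0]
    eta = np.hstack([np.zeros((m, 1)), X @ B.T])
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    ll = float(np.log(np.clip(P[np.arange(m), Y], 1e-300, None)).sum())
    ll -= 0.5 * ridge * float((B * B).sum())
    grad = np.empty((km1, p))
    for k in range(km1):
        grad[k] = X.T @ ((Y == k + 1).astype(float) - P[:, k + 1])
    grad -= ridge * B
    H = np.empty((km1 * p, km1 * p))
    for k in range(km1):
        for l in range(k, km1):
            w = P[:, k + 1] * ((k == l) - P[:, l + 1])
            blk = -(X.T * w) @ X
            H[k * p:(k + 1) * p, l * p:(l + 1) * p] = blk
            H[l * p:(l + 1) * p, k * p:(k + 1) * p] = blk.T
    H -= ridge * np.eye(km1 * p)
    return ll, grad.ravel(), H


def fit_multinomial(y: np.ndarray, X: np.ndarray, *, ridge: float = 0.0,
                    max_iter: int = 100, tol: float = 1e-10
                    ) -> MultinomialFit:
    """Maximum-likelihood multinomial logit (category 0 = reference).

    Newton iterations with step-halving; the log-likelihood is
    non-decreasing across accepted steps.  If the fit diverges (complete
    separation: unbounded coefficients or a singular information matrix)
    the model is refitted with ``ridge=1e-6`` and flagged.
    """
    y = np.asarray(y)
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need at least 2 observed categories")
    # map to 0..K-1 dense codes
    Y = np.searchsorted(cats, y)
    X = np.asarray(X, float)
    m, p = X.shape
    km1 = len(cats) - 1
    B = np.zeros((km1, p))
    ll_old = -np.inf
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, g, H = _loglik_grad_hess(B, X, Y, ridge)
        try:
            step = np.linalg.solve(H, -g).reshape(km1, p)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving so the log-likelihood never decreases
        t = 1.0
        for _ in range(40):
            ll_new = _loglik_grad_hess(B + t * step, X, Y, ridge)[0]
            if ll_new >= ll:
                break
            t /= 2
        B = B + t * step
        if np.abs(B).max() > 15:
            separation = True
            break
        if ll_new - ll_old < tol * (1 + abs(ll_new)) and it > 1:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if np.abs(B).max() > 15:
        separation = True
    if separation and ridge == 0.0:
        warnings.warn("apparent complete separation; refitting with a "
                      "ridge penalty of 1e-6")
        out = fit_multinomial(y, X, ridge=1e-6, max_iter=max_iter, tol=tol)
        out.separation = True
        return out
    ll, g, H = _loglik_grad_hess(B, X, Y, ridge)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(km1, p)
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full((km1, p), np.nan)
    return MultinomialFit(coef=B, se=se, loglik=ll, n_iter=it,
                          converged=converged, ridge=ridge,
                          separation=separation, categories=cats)
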