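"""Small, fast maximum-likelihood logistic regression.

The signature-selection stage refits logistic models hundreds of thousands
of times on tiny design matrices (tens of samples, a handful of features),
so the solver is a direct Newton iteration on a standardized design rather
than a general-purpose optimizer.  Fits are unpenalized; on (quasi-)
separated data the fit falls back to a small ridge and flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: ridge applied (on the standardized scale, intercept excluded) when the
#: unpenalized likelihood has no finite maximizer
RIDGE_FALLBACK = 1e-4

#: |standardized coefficient| beyond which the data are treated as separated
_SEPARATION_BOUND = 30.0


@dataclass
class LogisticModel:
    """Fitted model with coefficients on the original feature scale."""

    coef: np.ndarray
    intercept: float
    feature_names: tuple[str, ...]
    scores: np.ndarray  # in-sample predicted probabilities
    converged: bool
    ridge_used: float
    dropped: tuple[str, ...] = ()

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _newton(
    X1: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 60, tol: float = 1e-11
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson for the (optionally ridged) logistic log-likelihood.

    ``X1`` includes the intercept column first; the ridge never penalizes it.
    Returns (beta, converged); separation shows up as non-convergence or a
    runaway coefficient norm.
    """
    n, p = X1.shape
    beta = np.zeros(p)
    solve = np.linalg.solve
    for _ in range(max_iter):
        eta = X1 @ beta
        np.clip(eta, -35.0, 35.0, out=eta)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = X1.T @ (y - mu)
        h = (X1 * w[:, None]).T @ X1
        if ridge:
            grad[1:] -= ridge * beta[1:]
            h.flat[p + 1 :: p + 1] += ridge
        try:
            step = solve(h, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta += step
        m = np.abs(step).max()
        if not np.isfinite(m):
            return beta, False
        if m < tol:
            if ridge == 0.0 and p > 1 and np.abs(beta[1:]).max() > _SEPARATION_BOUND:
                return beta, False
            return beta, True
        if p > 1 and np.abs(beta[1:]).max() > 80.0:  # runaway norm: separation
            return beta, False
    return beta, False


def fit_logistic(
    X,
    y,
    feature_names: tuple[str, ...] | None = None,
    *,
    ridge: float = 0.0,
) -> LogisticModel:
    """Unpenalized ML logistic fit with ridge fallback on separation.

    Constant features are dropped with a warning.  Internally the design is
    standardized for conditioning; reported coefficients are transformed back
    to the original scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y).astype(float)
    if X.shape[0] != len(y):
        raise ValueError("X and y misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(p)
    )
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(np.asarray(names)[~keep])
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    mu = Xk.mean(axis=0)
    sdk = sd[keep]
    Z = (Xk - mu) / sdk
    X1 = np.column_stack([np.ones(n), Z])
    beta, converged = _newton(X1, y, ridge)
    ridge_used = ridge
    if not converged:
        beta, converged = _newton(X1, y, RIDGE_FALLBACK if ridge == 0.0 else ridge * 10)
        ridge_used = RIDGE_FALLBACK if ridge == 0.0 else ridge * 10
    coef_std = beta[1:]
    coef = np.zeros(p)
    coef[keep] = coef_std / sdk
    intercept = float(beta[0] - (coef_std * mu / sdk).sum())
    scores = expit(np.clip(X @ coef + intercept, -35.0, 35.0))
    return LogisticModel(
        coef=coef,
        intercept=intercept,
        feature_names=names,
        scores=scores,
        converged=converged,
        ridge_used=ridge_used,
        dropped=dropped,
    )


def batch_newton(
    Xs: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iteration over a stack of designs sharing the response.

    ``Xs`` has shape (C, n, p) with the intercept column first in each
    design.  Returns (betas (C, p), converged (C,)).  Used to evaluate all
    candidate feature additions of a forward-selection step in one pass;
    semantics per candidate match :func:`_newton`.
    """
    C, n, p = Xs.shape
    beta = np.zeros((C, p))
    conv = np.zeros(C, dtype=bool)
    active = np.arange(C)
    jitter = 1e-10  # keeps the batched solve from dying on one singular H
    for _ in range(max_iter):
        if not len(active):
            break
        Xa = Xs[active]
        ba = beta[active]
        eta = np.einsum("cnp,cp->cn", Xa, ba)
        np.clip(eta, -35.0, 35.0, out=eta)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = np.einsum("cnp,cn->cp", Xa, y[None, :] - mu)
        h = np.einsum("cnp,cn,cnq->cpq", Xa, w, Xa)
        if ridge:
            grad[:, 1:] -= ridge * ba[:, 1:]
            h[:, np.arange(1, p), np.arange(1, p)] += ridge
        h[:, np.arange(p), np.arange(p)] += jitter
        try:
            step = np.linalg.solve(h, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break  # leave remaining actives unconverged
        ba = ba + step
        beta[active] = ba
        m = np.abs(step).max(axis=1)
        m[~np.isfinite(m)] = np.inf
        done = m < tol
        if p > 1:
            coef_norm = np.abs(ba[:, 1:]).max(axis=1)
            runaway = coef_norm > 80.0
            sep_at_conv = done & (coef_norm > _SEPARATION_BOUND) & (ridge == 0.0)
        else:
            runaway = np.zeros(len(active), dtype=bool)
            sep_at_conv = np.zeros(len(active), dtype=bool)
        conv[active[done & ~sep_at_conv]] = True
        active = active[~(done | runaway)]
    return beta, conv


def fast_linear_scores(
    Z: np.ndarray, y: np.ndarray, cols: list[int]
) -> np.ndarray | None:
    """Linear predictor of a logistic fit on pre-standardized columns.

    Monotone in the predicted probability, hence interchangeable with it for
    rank statistics (AUC).  Returns None when even the ridged fit fails.
    Used by the forward-selection inner loop where only scores matter.
    """
    n = Z.shape[0]
    X1 = np.empty((n, len(cols) + 1))
    X1[:, 0] = 1.0
    X1[:, 1:] = Z[:, cols]
    beta, converged = _newton(X1, y, 0.0, max_iter=25, tol=1e-8)
    if not converged:
        beta, converged = _newton(X1, y, RIDGE_FALLBACK, max_iter=40, tol=1e-8)
        if not converged:
            return None
    return X1 @ beta
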