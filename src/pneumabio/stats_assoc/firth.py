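"""Firth penalised logistic regression (Jeffreys-prior penalty).

Maximises l(b) + 0.5 * log det I(b).  The penalised score is
U*(b) = X' (y - p + h * (0.5 - p)) with h the hat-matrix diagonal, solved
by damped Newton iterations; estimates stay finite under separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["FirthResult", "firth_logistic", "penalised_loglik"]

_Z95 = 1.959963984540054


@dataclass
class FirthResult:
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray           # on the coefficient scale
    ci_high: np.ndarray
    loglik_penalised: float
    n_iter: int
    converged: bool
    status: str = "ok"           # "ok" | "max_iter"

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)


def penalised_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Jeffreys-penalised log-likelihood at beta (the quantity maximised)."""
    eta = X @ beta
    p = expit(eta)
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * float(logdet)


def firth_logistic(
    X,
    y,
    add_intercept: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FirthResult:
    """Fit a Firth penalised logistic regression.

    ``X`` is the design matrix (an intercept column is prepended unless
    ``add_intercept`` is False).  Iterates until the penalised-score norm
    falls below ``tol``; Wald CIs from the inverse penalised information.
    Non-convergence returns the last iterate with ``status='max_iter'``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal: h_i = w_i * x_i' info^{-1} x_i
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.linalg.norm(score) < tol:
            converged = True
            break
        step = info_inv @ score
        # damp steps so the penalised likelihood never decreases
        ll0 = penalised_loglik(X, y, beta)
        lam = 1.0
        while lam > 1e-4 and penalised_loglik(X, y, beta + lam * step) < ll0:
            lam *= 0.5
        beta = beta + lam * step

    p = expit(X @ beta)
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return FirthResult(
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        loglik_penalised=penalised_loglik(X, y, beta),
        n_iter=it,
        converged=converged,
        status="ok" if converged else "max_iter",
    )
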