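"""Maximum-likelihood logistic regression via Newton/IRLS.

Two entry points: :func:`fit_logistic` for one design matrix, and
:func:`fit_logistic_batch` which fits many small designs sharing one outcome
vector in a single vectorised Newton loop — the permutation epistasis scan
refits hundreds of two-locus models per shuffle, so per-fit overhead matters.

Wald z-statistics use the observed-information standard errors; quasi-perfect
separation is detected by coefficient blow-up and reported as a
non-converged fit rather than returned silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: |coefficient| beyond which the likelihood is treated as separated.
_SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """Result of one logistic maximum-likelihood fit."""

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n_iter: int
    llf: float
    n_obs: int

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])


def _loglik(X, y, w, beta):
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(X, y, weights=None, tol: float = 1e-8,
                 max_iter: int = 50) -> LogisticFit:
    """Fit P(y=1) = logistic(X @ beta) by Newton-Raphson.

    ``X`` must include the intercept column.  Rows may be down-weighted (or
    excluded with weight 0) via ``weights``.  Convergence is declared when
    the score max-norm falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    n_eff = int((w > 0).sum())

    beta = np.zeros(k)
    ybar = float(np.sum(w * y) / np.sum(w))
    ybar = min(max(ybar, 1e-12), 1 - 1e-12)
    beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = (X * v[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        ll0 = _loglik(X, y, w, beta)
        new = beta + step
        # step-halving keeps Newton monotone on flat/ill-conditioned surfaces
        for _ in range(20):
            if _loglik(X, y, w, new) >= ll0 - 1e-12:
                break
            step *= 0.5
            new = beta + step
        beta = new
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            converged = False
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    v = w * mu * (1.0 - mu)
    info = (X * v[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
        converged = False
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / bse
    p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, bse, z, p, converged, it, _loglik(X, y, w, beta), n_eff)


def fit_logistic_batch(Xb, y, weights=None, tol: float = 1e-8,
                       max_iter: int = 30):
    """Fit B logistic models with designs ``Xb[b]`` against a shared ``y``.

    Parameters
    ----------
    Xb : array, shape (B, n, k)
        One design per model; missing rows must be zero-filled and masked out
        through ``weights``.
    y : array, shape (n,)
    weights : array, shape (B, n), optional
        Per-model row weights (0 drops a row).

    Returns
    -------
    params, bse : arrays of shape (B, k); converged : bool array (B,).
    """
    Xb = np.asarray(Xb, dtype=float)
    y = np.asarray(y, dtype=float)
    B, n, k = Xb.shape
    w = np.ones((B, n)) if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros((B, k))
    ybar = np.clip((w * y).sum(axis=1) / w.sum(axis=1), 1e-12, 1 - 1e-12)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    active = np.ones(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    eye = np.eye(k) * 1e-10

    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.einsum("bnk,bk->bn", Xb, beta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = w * mu * (1.0 - mu)
        resid = w * (y[None, :] - mu)
        score = np.einsum("bnk,bn->bk", Xb, resid)
        info = np.einsum("bnk,bn,bnl->bkl", Xb, v, Xb) + eye
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(info[b], score[b], rcond=None)[0]
                             for b in range(B)])
        beta[active] += step[active]
        done = np.abs(score).max(axis=1) < tol
        blown = np.abs(beta).max(axis=1) > _SEPARATION_BOUND
        converged |= active & done & ~blown
        active &= ~done & ~blown

    eta = np.einsum("bnk,bk->bn", Xb, beta)
    mu = 1.0 / (1.0 + np.exp(-eta))
    v = w * mu * (1.0 - mu)
    info = np.einsum("bnk,bn,bnl->bkl", Xb, v, Xb) + np.eye(k) * 1e-10
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((B, k, k), np.nan)
    bse = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0, None))
    converged &= np.isfinite(beta).all(axis=1) & np.isfinite(bse).all(axis=1)
    return beta, bse, converged
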