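"""Quasi-Poisson generalized linear model by IRLS, and the Q-AIC.

The quasi-Poisson model keeps the Poisson log-likelihood and log link but
inflates the coefficient covariance by a dispersion parameter estimated from
the Pearson statistic, phi = X^2 / (n - k).  The Q-AIC used to rank candidate
event definitions penalizes the quasi-likelihood fit for that overdispersion:

    QAIC = -2 * loglik + 2 * phi * k          (default)
    QAIC = -2 * loglik / phi + 2 * k          (variant 'scaled')

Only within-dataset comparisons are made, so the variant affects nothing
downstream; both are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class GLMFit:
    """Result of a quasi-Poisson fit.

    ``beta`` has one entry per design column; aliased (dropped) columns carry
    NaN.  ``cov`` is the dispersion-scaled covariance, NaN outside the kept
    block.  ``k`` counts estimated parameters (kept columns only).
    """

    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    loglik: float
    k: int
    converged: bool
    n: int
    deviance: float
    kept: np.ndarray
    dev_history: list[float]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _detect_aliased(X: np.ndarray) -> np.ndarray:
    """Boolean mask of linearly independent columns, via pivoted QR."""
    n, p = X.shape
    if p == 0:
        return np.zeros(0, dtype=bool)
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    kept = np.zeros(p, dtype=bool)
    kept[piv[:rank]] = True
    return kept


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    strict: bool = False,
) -> GLMFit:
    """Fit a log-link quasi-Poisson GLM by iteratively reweighted least squares.

    The coefficients maximize the Poisson likelihood; the dispersion is the
    Pearson chi-square over residual degrees of freedom; the covariance is
    ``phi * (X' W X)^-1``.  Step-halving keeps the Poisson deviance
    non-increasing across iterations.  Rank-deficient designs have their
    aliased columns dropped with a logged warning; non-convergence raises in
    ``strict`` mode and otherwise returns ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be a 2-D design aligned with y")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("y must be nonnegative and finite")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    n, p = X.shape
    offs = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    kept = _detect_aliased(X)
    if not kept.all():
        logger.warning("dropping %d aliased design column(s)", (~kept).sum())
    Xk = X[:, kept]
    k = Xk.shape[1]

    # start: intercept at log(mean(y) + 0.5), other coefficients zero
    beta = np.zeros(k)
    const = np.flatnonzero(np.all(Xk == Xk[0], axis=0) & (Xk[0] != 0.0))
    mu0 = np.log(y.mean() + 0.5)
    if const.size:
        beta[const[0]] = mu0 / Xk[0, const[0]]
        eta = Xk @ beta + offs
    else:
        eta = np.full(n, mu0) + offs
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu)
    score_scale = 1.0 + float(np.abs(y).sum())
    dev_history = [dev]

    converged = False
    for _ in range(max_iter):
        w = mu
        z = (eta - offs) + (y - mu) / mu
        xw = Xk * w[:, None]
        xtwx = xw.T @ Xk
        xtwz = xw.T @ z
        try:
            beta_new = scipy.linalg.solve(xtwx, xtwz, assume_a="pos")
        except scipy.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtwx, xtwz, rcond=None)[0]
        # step-halving: never let the deviance increase
        step = beta_new - beta
        frac = 1.0
        for _half in range(30):
            cand = beta + frac * step
            eta_c = Xk @ cand + offs
            mu_c = np.exp(np.clip(eta_c, -700, 700))
            dev_c = _poisson_deviance(y, mu_c)
            if np.isfinite(dev_c) and dev_c <= dev * (1 + 1e-12) + 1e-12:
                break
            frac *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        dev_prev, dev = dev, dev_c
        dev_history.append(dev)
        score = Xk.T @ (y - mu)
        if np.max(np.abs(score)) < tol * score_scale and (
            abs(dev_prev - dev) <= 1e-10 * (abs(dev) + 1.0)
        ):
            converged = True
            break
    if not converged:
        msg = "quasi-Poisson IRLS did not converge"
        if strict:
            raise RuntimeError(msg)
        logger.warning(msg)

    pearson = float(np.sum((y - mu) ** 2 / mu))
    dof = max(n - k, 1)
    dispersion = pearson / dof
    if dispersion < DISPERSION_FLOOR:
        logger.warning("dispersion %.3g clipped to floor", dispersion)
        dispersion = DISPERSION_FLOOR
    xw = Xk * mu[:, None]
    xtwx = xw.T @ Xk
    try:
        cov_k = dispersion * scipy.linalg.inv(xtwx)
    except scipy.linalg.LinAlgError:
        cov_k = dispersion * np.linalg.pinv(xtwx)

    beta_full = np.full(p, np.nan)
    beta_full[kept] = beta
    cov_full = np.full((p, p), np.nan)
    cov_full[np.ix_(kept, kept)] = cov_k
    return GLMFit(
        beta=beta_full,
        cov=cov_full,
        dispersion=dispersion,
        loglik=_poisson_loglik(y, mu),
        k=k,
        converged=converged,
        n=n,
        deviance=dev,
        kept=kept,
        dev_history=dev_history,
    )


def qaic(fit: GLMFit, variant: str = "penalty") -> float:
    """Quasi-Poisson AIC of a converged fit.

    ``'penalty'``: -2*loglik + 2*phi*k (reduces to ordinary AIC at phi=1);
    ``'scaled'``: -2*loglik/phi + 2*k.
    """
    if not fit.converged:
        raise ValueError("Q-AIC requires a converged fit")
    if fit.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if variant == "penalty":
        return -2.0 * fit.loglik + 2.0 * fit.dispersion * fit.k
    if variant == "scaled":
        return -2.0 * fit.loglik / fit.dispersion + 2.0 * fit.k
    raise ValueError(f"unknown Q-AIC variant {variant!r}")
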