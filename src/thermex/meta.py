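"""Second stage: REML random-effects meta-analysis and meta-regression.

Community-specific log relative risks ``b_i`` with sampling variances ``v_i``
are pooled under the random-effects model ``b_i ~ N(mu, v_i + tau^2)``.  The
between-community variance tau^2 maximizes the restricted (residual) maximum
likelihood; the pooled mean is the inverse-variance weighted average with
weights ``1/(v_i + tau^2)``.  Heterogeneity is summarized by Cochran's Q and
I^2.  Meta-regression adds community-level predictors to the mean model and
reports the slope per interquartile-range increase on the percentage-change
scale, along with the residual tau^2 and the share of total variance that is
between-study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

Z975 = 1.959964  # standard normal 97.5th percentile


def pct_change(beta: float, se: float) -> tuple[float, float, float]:
    """Percentage change 100*(exp(beta)-1) with a 95% Wald interval."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    pct = 100.0 * (np.exp(beta) - 1.0)
    lo = 100.0 * (np.exp(beta - Z975 * se) - 1.0)
    hi = 100.0 * (np.exp(beta + Z975 * se) - 1.0)
    return float(pct), float(lo), float(hi)


@dataclass
class PooledEffect:
    beta: float
    se: float
    pct: float
    pct_lo: float
    pct_hi: float
    tau2: float
    Q: float
    Q_df: int
    Q_p: float
    I2: float
    k: int


@dataclass
class MetaRegResult:
    predictor: str
    iqr: float
    slope: float
    slope_se: float
    pct_per_iqr: float
    pct_lo: float
    pct_hi: float
    p_value: float
    tau2_res: float
    pct_between_variance: float
    k: int


def _check_inputs(betas: np.ndarray, variances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.shape != v.shape or b.ndim != 1:
        raise ValueError("betas and variances must be aligned 1-D arrays")
    if np.any(v <= 0) or not np.all(np.isfinite(b)) or not np.all(np.isfinite(v)):
        raise ValueError("variances must be positive and all inputs finite")
    return b, v


def reml_loglik(tau2: float, betas: np.ndarray, variances: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model (up to a constant)."""
    w = 1.0 / (variances + tau2)
    mu = np.sum(w * betas) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(variances + tau2))
        + np.log(np.sum(w))
        + np.sum(w * (betas - mu) ** 2)
    )


def _reml_tau2(betas: np.ndarray, variances: np.ndarray) -> float:
    """Maximize the REML log-likelihood in tau^2 over [0, 10*var(betas)]."""
    hi = max(10.0 * float(np.var(betas)), 10.0 * float(np.max(variances)), 1e-6)
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(t, betas, variances),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    # the boundary tau2=0 is not interior; take it if it does at least as well
    if reml_loglik(0.0, betas, variances) >= reml_loglik(tau2, betas, variances):
        tau2 = 0.0
    return tau2


def cochran_q(betas: np.ndarray, variances: np.ndarray) -> tuple[float, int]:
    """Cochran's heterogeneity statistic under fixed-effect weights 1/v."""
    b, v = _check_inputs(betas, variances)
    if b.size < 2:
        raise ValueError("Cochran's Q needs at least two studies")
    w = 1.0 / v
    mu_fe = np.sum(w * b) / np.sum(w)
    return float(np.sum(w * (b - mu_fe) ** 2)), int(b.size - 1)


def i_squared(Q: float, df: int) -> float:
    """I^2 heterogeneity percentage, truncated below at zero."""
    if df < 1:
        raise ValueError("df must be at least 1")
    if Q <= 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def meta_reml(betas: np.ndarray, variances: np.ndarray) -> PooledEffect:
    """REML random-effects pooling with heterogeneity statistics."""
    b, v = _check_inputs(betas, variances)
    k = b.size
    if k == 0:
        raise ValueError("no studies to pool")
    if k == 1:
        logger.warning("single study: pass-through pooling with tau2=0")
        pct, lo, hi = pct_change(float(b[0]), float(np.sqrt(v[0])))
        return PooledEffect(
            beta=float(b[0]), se=float(np.sqrt(v[0])), pct=pct, pct_lo=lo,
            pct_hi=hi, tau2=0.0, Q=0.0, Q_df=0, Q_p=float("nan"), I2=0.0, k=1,
        )
    tau2 = _reml_tau2(b, v)
    w = 1.0 / (v + tau2)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    Q, df = cochran_q(b, v)
    pct, lo, hi = pct_change(beta, se)
    return PooledEffect(
        beta=beta, se=se, pct=pct, pct_lo=lo, pct_hi=hi, tau2=tau2,
        Q=Q, Q_df=df, Q_p=float(stats.chi2.sf(Q, df)),
        I2=i_squared(Q, df), k=k,
    )


def z_diff_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sided Z-test for a difference between two independent subgroup effects."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _reml_loglik_reg(
    tau2: float, b: np.ndarray, v: np.ndarray, X: np.ndarray
) -> float:
    w = 1.0 / (v + tau2)
    xtwx = (X * w[:, None]).T @ X
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ b)
    r = b - X @ coef
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r**2))


def typical_within_variance(variances: np.ndarray) -> float:
    """Higgins-Thompson 'typical' within-study variance s^2.

    s^2 = (k-1) * sum(w) / ((sum w)^2 - sum(w^2)) with w = 1/v.
    """
    v = np.asarray(variances, dtype=float)
    w = 1.0 / v
    k = v.size
    return float((k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2)))


def meta_regression(
    betas: np.ndarray,
    variances: np.ndarray,
    x: np.ndarray,
    iqr: float | None = None,
    predictor: str = "x",
) -> MetaRegResult:
    """Univariable mixed-effects meta-regression of effects on one predictor.

    The residual between-community variance tau2_res is REML-profiled; the
    slope is reported per IQR increase of the predictor on the
    percentage-change scale with a Wald interval and p-value.  The share of
    total variance that is between-study is tau2_res / (tau2_res + s^2) with
    s^2 the typical within-study variance.
    """
    b, v = _check_inputs(betas, variances)
    x = np.asarray(x, dtype=float)
    if x.shape != b.shape:
        raise ValueError("predictor misaligned with effects")
    if b.size < 3:
        raise ValueError("meta-regression needs at least three communities")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor must be finite")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    if iqr is None:
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    X = np.column_stack([np.ones(b.size), x])

    hi = max(10.0 * float(np.var(b)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik_reg(t, b, v, X),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    if _reml_loglik_reg(0.0, b, v, X) >= _reml_loglik_reg(tau2, b, v, X):
        tau2 = 0.0

    w = 1.0 / (v + tau2)
    xtwx = (X * w[:, None]).T @ X
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ b)
    cov = np.linalg.inv(xtwx)
    slope = float(coef[1])
    slope_se = float(np.sqrt(cov[1, 1]))
    zstat = slope / slope_se
    p = 2.0 * stats.norm.sf(abs(zstat))
    pct = 100.0 * (np.exp(slope * iqr) - 1.0)
    lo = 100.0 * (np.exp((slope - Z975 * slope_se) * iqr) - 1.0)
    hi_ci = 100.0 * (np.exp((slope + Z975 * slope_se) * iqr) - 1.0)
    if iqr < 0:  # a negative IQR flips the interval
        lo, hi_ci = hi_ci, lo
    s2 = typical_within_variance(v)
    return MetaRegResult(
        predictor=predictor, iqr=float(iqr), slope=slope, slope_se=slope_se,
        pct_per_iqr=float(pct), pct_lo=float(lo), pct_hi=float(hi_ci),
        p_value=float(p), tau2_res=tau2,
        pct_between_variance=float(100.0 * tau2 / (tau2 + s2)), k=b.size,
    )


def pool_stratified(
    effects_by_stratum: dict[str, tuple[np.ndarray, np.ndarray]],
    contrasts: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, PooledEffect], list[dict]]:
    """Pool each stratum independently and Z-test designated contrasts.

    ``effects_by_stratum`` maps stratum label to (betas, variances).  Strata
    with fewer than two communities are skipped with a warning.  Returns the
    per-stratum pooled effects and a list of contrast rows.
    """
    pooled: dict[str, PooledEffect] = {}
    for label, (b, v) in effects_by_stratum.items():
        b = np.asarray(b, dtype=float)
        if b.size < 2:
            logger.warning("stratum %r has <2 communities; skipped", label)
            continue
        pooled[label] = meta_reml(b, v)
    rows: list[dict] = []
    for a, c in contrasts or []:
        if a not in pooled or c not in pooled:
            continue
        z, p = z_diff_test(pooled[a].beta, pooled[a].se, pooled[c].beta, pooled[c].se)
        rows.append({"stratum_a": a, "stratum_b": c, "z": z, "p": p})
    return pooled, rows
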