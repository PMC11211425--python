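"""Natural cubic spline bases and the two-dimensional DLNM cross-basis.

The cross-basis encodes a daily variable's nonlinear lagged exposure history:
row *t*, column *(i, j)* equals sum over lags ``l = 0..max_lag`` of
``B_var,i(x[t-l]) * B_lag,j(l)``, where ``B_var`` is a natural cubic spline in
the variable dimension and ``B_lag`` a natural cubic spline (with intercept)
over the lag axis.  The first ``max_lag`` rows of a series have incomplete
lag history and are flagged for exclusion from the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SplineSpec:
    """Specification of a natural cubic spline basis.

    ``df`` is the number of basis columns.  Without an intercept column the
    basis has ``df - 1`` interior knots; with one (the lag dimension) it has
    ``df - 2``.  ``interior_knots=None`` defers placement to the knot rule of
    the dimension (quantiles of the data for a variable, equally spaced on
    the log(lag+1) scale for lags).
    """

    df: int
    boundary_knots: tuple[float, float] | None = None
    interior_knots: np.ndarray | None = None
    intercept: bool = False

    def n_interior(self) -> int:
        return self.df - 1 - int(self.intercept)


def _ns_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline design (no intercept column).

    ``knots`` includes the two boundary knots; the basis has ``len(knots)-1``
    columns, is cubic between knots and linear beyond the boundaries, and its
    span together with an intercept contains all linear functions.
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("spline knots must be strictly increasing (no duplicates)")
    x = np.asarray(x, dtype=float)
    # affine rescale to the unit interval for numerical conditioning; the
    # column space, natural behaviour beyond the boundaries and column count
    # are invariant under this change of variable
    span = knots[-1] - knots[0]
    x = (x - knots[0]) / span
    knots = (knots - knots[0]) / span
    K = knots.size
    cols = [x]
    if K >= 3:
        last = knots[K - 1]
        pen = knots[K - 2]

        def d(xi: float) -> np.ndarray:
            return (
                np.clip(x - xi, 0.0, None) ** 3 - np.clip(x - last, 0.0, None) ** 3
            ) / (last - xi)

        d_pen = d(pen)
        for k in range(K - 2):
            cols.append(d(knots[k]) - d_pen)
    return np.column_stack(cols)


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate a natural cubic spline basis at ``x``.

    Knot rule: boundary knots at the range of ``x`` unless given; interior
    knots at equally spaced quantiles of ``x`` unless given.
    """
    if spec.df < 2:
        raise ValueError("a natural cubic spline basis needs df >= 2")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    lo, hi = (
        spec.boundary_knots
        if spec.boundary_knots is not None
        else (float(x.min()), float(x.max()))
    )
    if spec.interior_knots is not None:
        interior = np.asarray(spec.interior_knots, dtype=float)
    else:
        probs = np.linspace(0.0, 1.0, spec.n_interior() + 2)[1:-1]
        interior = np.quantile(x, probs)
    if interior.size and (interior.min() <= lo or interior.max() >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary knots")
    knots = np.concatenate([[lo], interior, [hi]])
    basis = _ns_design(x, knots)
    if spec.intercept:
        basis = np.column_stack([np.ones(x.size), basis])
    if basis.shape[1] != spec.df:
        raise ValueError(
            f"basis has {basis.shape[1]} columns, expected df={spec.df}"
        )
    return basis


def lag_knots(max_lag: int, df: int) -> SplineSpec:
    """Spline specification for the lag dimension of a cross-basis.

    The lag basis carries an intercept (so a lag-constant effect is in the
    model space); its ``df - 2`` interior knots are equally spaced on the
    log(lag+1) scale between the boundary knots 0 and ``max_lag``.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1 day")
    if df < 2:
        raise ValueError("lag basis needs df >= 2")
    if df > max_lag + 1:
        raise ValueError(f"df={df} too large for max_lag={max_lag}")
    n_int = df - 2
    grid = np.linspace(0.0, np.log(max_lag + 1.0), n_int + 2)[1:-1]
    interior = np.exp(grid) - 1.0
    return SplineSpec(
        df=df,
        boundary_knots=(0.0, float(max_lag)),
        interior_knots=interior,
        intercept=True,
    )


@dataclass
class CrossBasis:
    """n_days x (df_var * df_lag) matrix of lagged spline exposure history."""

    matrix: np.ndarray
    var_spec: SplineSpec
    lag_spec: SplineSpec | None
    max_lag: int
    complete: np.ndarray = field(repr=False)  # rows with full lag history

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


def build_cross_basis(
    x: np.ndarray,
    var_spec: SplineSpec | str,
    lag_spec: SplineSpec | None,
    max_lag: int,
) -> CrossBasis:
    """Build the bi-dimensional cross-basis of a daily series.

    ``var_spec='linear'`` uses the identity (one linear column) in the
    variable dimension.  ``lag_spec=None`` uses a saturated lag basis (one
    indicator column per lag), under which the cross-basis model is exactly
    the unconstrained distributed-lag model.  The first ``max_lag`` rows are
    flagged incomplete and filled with NaN.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    if isinstance(var_spec, str):
        if var_spec != "linear":
            raise ValueError(f"unknown variable basis {var_spec!r}")
        var_spec = SplineSpec(df=1)
        var_basis = x[:, None]
    else:
        var_basis = natural_cubic_basis(x, var_spec)  # n x dv
    lags = np.arange(max_lag + 1, dtype=float)
    if lag_spec is None:
        lag_basis = np.eye(max_lag + 1)
    else:
        lag_basis = natural_cubic_basis(lags, lag_spec)  # (L+1) x dl
    dv = var_basis.shape[1]
    dl = lag_basis.shape[1]
    out = np.zeros((n, dv, dl))
    for l in range(max_lag + 1):
        shifted = np.empty((n, dv))
        shifted[l:] = var_basis[: n - l]
        shifted[:l] = np.nan
        out += np.where(np.isnan(shifted[:, :, None]), 0.0, shifted[:, :, None]) * lag_basis[l][None, None, :]
    matrix = out.reshape(n, dv * dl)
    complete = np.ones(n, dtype=bool)
    complete[:max_lag] = False
    matrix[~complete] = np.nan
    return CrossBasis(
        matrix=matrix,
        var_spec=var_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        complete=complete,
    )
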