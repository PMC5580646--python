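"""Smooth exposure-response curves by penalized regression splines.

Relative mortality is regressed on the thermal index with a cubic
B-spline basis and a second-derivative (curvature) roughness penalty;
the smoothing parameter is chosen by generalized cross-validation.  The
fit is a Gaussian additive model with a single univariate smooth.  The
penalty null space contains exactly the linear
functions, so as the smoothing parameter grows the fit converges to the
ordinary least-squares line.

Pointwise 95% bands use the Bayesian posterior covariance
sigma^2 (B'B + lambda S)^{-1}, the standard choice for penalized splines,
whose across-the-function coverage is close to nominal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline


@dataclass
class CurveEstimate:
    """A fitted exposure-response curve on an even exposure grid."""

    grid: np.ndarray           # degC
    fit: np.ndarray            # % relative mortality
    band_low: np.ndarray
    band_high: np.ndarray
    effective_df: float
    smoothing_parameter: float
    period: str = "all"
    age_group: str = "all"


def _knots(x_min: float, x_max: float, basis_dim: int, degree: int = 3) -> np.ndarray:
    """Open knot vector with equally spaced interior knots."""
    n_interior = basis_dim - degree - 1
    interior = np.linspace(x_min, x_max, n_interior + 2)[1:-1]
    return np.concatenate([[x_min] * (degree + 1), interior,
                           [x_max] * (degree + 1)])


def _design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _curvature_penalty(knots: np.ndarray, basis_dim: int,
                       degree: int = 3) -> np.ndarray:
    """S_ij = integral of B_i'' B_j'' over the knot span.

    The second derivative of a cubic B-spline is piecewise linear, so the
    integrand is piecewise quadratic and two-point Gauss-Legendre
    quadrature per inter-knot interval is exact.
    """
    spans = np.unique(knots)
    # Gauss-Legendre nodes/weights on [-1, 1]
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    gl_w = np.array([1.0, 1.0])
    quad_x, quad_w = [], []
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        quad_x.extend((a + b) / 2.0 + half * gl_x)
        quad_w.extend(half * gl_w)
    quad_x = np.asarray(quad_x)
    quad_w = np.asarray(quad_w)
    d2 = np.empty((len(quad_x), basis_dim))
    for i in range(basis_dim):
        coef = np.zeros(basis_dim)
        coef[i] = 1.0
        d2[:, i] = BSpline(knots, coef, degree).derivative(2)(quad_x)
    return (d2 * quad_w[:, None]).T @ d2


def _fit_at(lam: float, bt_b: np.ndarray, bt_y: np.ndarray,
            penalty: np.ndarray):
    a = bt_b + lam * penalty
    a_inv = np.linalg.inv(a)
    beta = a_inv @ bt_y
    edf = float(np.trace(a_inv @ bt_b))
    return beta, a_inv, edf


def fit_curve(pairs, basis_dim: int = 10, criterion: str = "gcv",
              smoothing_parameter: float | None = None,
              grid_size: int = 200, period: str = "all",
              age_group: str | None = None) -> CurveEstimate:
    """Fit a penalized-spline exposure-response curve with 95% bands.

    ``pairs`` is a DataFrame with ``exposure``/``response`` columns (or a
    tuple of arrays).  ``basis_dim`` is the number of B-spline basis
    functions (default 10); the smoothing parameter is chosen by GCV
    unless given explicitly.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["exposure"].to_numpy(dtype=float)
        y = pairs["response"].to_numpy(dtype=float)
        if age_group is None and "age_group" in pairs.columns and len(pairs):
            age_group = str(pairs["age_group"].iloc[0])
    else:
        x, y = (np.asarray(v, dtype=float) for v in pairs)
    age_group = age_group or "all"
    if criterion != "gcv":
        raise ValueError(f"unsupported smoothing criterion {criterion!r}")
    n = len(x)
    if n < basis_dim + 5:
        raise ValueError(f"need at least basis_dim + 5 = {basis_dim + 5} pairs, "
                         f"got {n}")
    x_min, x_max = float(x.min()), float(x.max())
    if x_min == x_max:
        raise ValueError("exposure is constant; no curve can be fitted")
    knots = _knots(x_min, x_max, basis_dim)
    design = _design(x, knots)
    if np.linalg.matrix_rank(design.T @ design) < basis_dim:
        raise ValueError(
            f"rank-deficient design: basis_dim={basis_dim} is too large for "
            "the exposure distribution")
    penalty = _curvature_penalty(knots, basis_dim)
    bt_b = design.T @ design
    bt_y = design.T @ y
    yty = float(y @ y)

    if smoothing_parameter is not None and np.isinf(smoothing_parameter):
        # exact infinite-smoothing limit: the curvature penalty annihilates
        # exactly the linear functions, so the fit is the OLS line
        grid_x = np.linspace(x_min, x_max, grid_size)
        xm = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(xm, y, rcond=None)
        resid = y - xm @ coef
        sigma2 = float(resid @ resid) / (n - 2)
        cov2 = sigma2 * np.linalg.inv(xm.T @ xm)
        gm = np.column_stack([np.ones(grid_size), grid_x])
        fit = gm @ coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", gm, cov2, gm))
        z = 1.959963984540054
        return CurveEstimate(grid=grid_x, fit=fit, band_low=fit - z * se,
                             band_high=fit + z * se, effective_df=2.0,
                             smoothing_parameter=np.inf, period=period,
                             age_group=age_group)

    def gcv(log_lam: float) -> float:
        beta, _, edf = _fit_at(10.0 ** log_lam, bt_b, bt_y, penalty)
        rss = yty - 2.0 * beta @ bt_y + beta @ bt_b @ beta
        return n * rss / (n - edf) ** 2

    if smoothing_parameter is None:
        grid = np.linspace(-8.0, 12.0, 41)
        scores = [gcv(g) for g in grid]
        best = grid[int(np.argmin(scores))]
        res = optimize.minimize_scalar(gcv, bounds=(best - 1.0, best + 1.0),
                                       method="bounded")
        lam = float(10.0 ** res.x)
    else:
        lam = float(smoothing_parameter)

    beta, a_inv, edf = _fit_at(lam, bt_b, bt_y, penalty)
    rss = yty - 2.0 * beta @ bt_y + beta @ bt_b @ beta
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * a_inv

    grid_x = np.linspace(x_min, x_max, grid_size)
    bg = _design(grid_x, knots)
    fit = bg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", bg, cov, bg), 0.0))
    z = 1.959963984540054
    return CurveEstimate(grid=grid_x, fit=fit, band_low=fit - z * se,
                         band_high=fit + z * se, effective_df=edf,
                         smoothing_parameter=lam, period=period,
                         age_group=age_group)


def evaluate_curve(curve: CurveEstimate, x):
    """Linear interpolation of fit and band on the stored grid.

    Raises outside the grid range; the curve is not extrapolated.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if (arr < curve.grid[0]).any() or (arr > curve.grid[-1]).any():
        raise ValueError(
            f"x outside the fitted exposure range "
            f"[{curve.grid[0]:.3g}, {curve.grid[-1]:.3g}]")
    fit = np.interp(arr, curve.grid, curve.fit)
    lo = np.interp(arr, curve.grid, curve.band_low)
    hi = np.interp(arr, curve.grid, curve.band_high)
    if np.ndim(x) == 0:
        return float(fit[0]), (float(lo[0]), float(hi[0]))
    return fit, (lo, hi)


def curve_table(curve: CurveEstimate) -> pd.DataFrame:
    """The curve as a tidy frame for CSV output."""
    return pd.DataFrame({
        "age_group": curve.age_group, "period": curve.period,
        "exposure": curve.grid, "fit": curve.fit,
        "band_low": curve.band_low, "band_high": curve.band_high,
    })
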