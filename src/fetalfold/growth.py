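"""Cohort-level developmental trajectory fits.

Sulcal depth grows sigmoidally over gestational weeks 24-36; mean
tissue/fluid fractions follow smooth quadratic trends.  This module fits
a 4-parameter logistic

    y = L + (U - L) / (1 + exp(-k (ga - g0)))

by bounded nonlinear least squares with deterministic data-quantile
initialisation, and an ordinary-least-squares quadratic on the
(1, ga, ga^2) basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    pass


@dataclass
class SigmoidFit:
    """4-parameter logistic fit result.

    ``lower``/``upper`` are the asymptotes (metric units), ``inflection_ga``
    the midpoint in weeks, ``rate`` the growth rate per week.  ``degenerate``
    flags fits with essentially no dynamic range (U - L ~ 0), for which the
    remaining parameters are not interpretable.
    """

    lower: float
    upper: float
    inflection_ga: float
    rate: float
    residual_se: float
    degenerate: bool = False

    def predict(self, ga: np.ndarray) -> np.ndarray:
        return logistic(np.asarray(ga, dtype=float), self.lower, self.upper,
                        self.inflection_ga, self.rate)


@dataclass
class PolyFit:
    """Quadratic OLS fit: coefficients (intercept, linear, quadratic)."""

    coefficients: np.ndarray
    residual_se: float

    def predict(self, ga: np.ndarray) -> np.ndarray:
        ga = np.asarray(ga, dtype=float)
        c = self.coefficients
        return c[0] + c[1] * ga + c[2] * ga**2


def logistic(ga, lower, upper, g0, k):
    """4-parameter logistic curve."""
    return lower + (upper - lower) / (1.0 + np.exp(-k * (np.asarray(ga) - g0)))


def fit_sigmoid(ga: np.ndarray, y: np.ndarray,
                degenerate_tol: float = 1e-8) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of y against gestational age.

    Initialisation is deterministic from the data: L = min(y), U = max(y),
    g0 = GA where y first crosses the half range, k = 4 / GA span.  Bounds
    keep the asymptotes within the data range +/- 50% of the range and the
    rate in (0, 5].  Requires >= 5 subjects spanning > 4 weeks.  Constant
    y is flagged degenerate (no fit attempted); non-convergence raises
    :class:`FitError` with the solver diagnostics.
    """
    ga = np.asarray(ga, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if ga.shape != y.shape or ga.ndim != 1:
        raise FitError("ga and y must be 1-D arrays of equal length")
    if len(ga) < 5:
        raise FitError("need at least 5 subjects")
    span = float(np.ptp(ga))
    if span <= 4.0:
        raise FitError("gestational ages must span more than 4 weeks")
    y_min, y_max = float(y.min()), float(y.max())
    y_range = y_max - y_min
    if y_range <= degenerate_tol * max(1.0, abs(y_max), abs(y_min)):
        return SigmoidFit(y_min, y_max, float(np.median(ga)), 0.0,
                          residual_se=float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
                          degenerate=True)
    order = np.argsort(ga, kind="stable")
    half = y_min + 0.5 * y_range
    crossing = ga[order][np.searchsorted(
        np.maximum.accumulate(y[order]), half)] if np.any(y[order] >= half) \
        else float(np.median(ga))
    x0 = np.array([y_min, y_max, float(crossing), 4.0 / span])
    slack = 0.5 * y_range
    lb = np.array([y_min - slack, y_min - slack, ga.min() - span, 1e-6])
    ub = np.array([y_max + slack, y_max + slack, ga.max() + span, 5.0])
    x0 = np.clip(x0, lb, ub)

    def residuals(params):
        return logistic(ga, *params) - y

    sol = least_squares(residuals, x0, bounds=(lb, ub),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    if not sol.success:
        raise FitError(
            f"sigmoid fit did not converge (status {sol.status}: {sol.message}); "
            f"initialisation {x0.tolist()}"
        )
    lower, upper, g0, k = sol.x
    dof = max(len(y) - 4, 1)
    residual_se = float(np.sqrt(2.0 * sol.cost / dof))
    degenerate = bool(
        abs(upper - lower) <= degenerate_tol * max(1.0, abs(upper), abs(lower)))
    return SigmoidFit(float(lower), float(upper), float(g0), float(k),
                      residual_se, degenerate=degenerate)


def fit_poly2(ga: np.ndarray, y: np.ndarray) -> PolyFit:
    """Ordinary least squares on the (1, ga, ga^2) basis.

    Requires at least 3 distinct GA values (otherwise the design is
    rank-deficient and the fit is refused).
    """
    ga = np.asarray(ga, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if ga.shape != y.shape or ga.ndim != 1:
        raise FitError("ga and y must be 1-D arrays of equal length")
    if len(np.unique(ga)) < 3:
        raise FitError("need at least 3 distinct gestational ages")
    design = np.column_stack([np.ones_like(ga), ga, ga**2])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient quadratic design")
    resid = y - design @ coef
    dof = max(len(y) - 3, 1)
    return PolyFit(coef, float(np.sqrt(resid @ resid / dof)))


__all__ = ["FitError", "SigmoidFit", "PolyFit", "logistic",
           "fit_sigmoid", "fit_poly2"]
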