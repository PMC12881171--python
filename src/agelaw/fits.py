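"""Least-squares curve fits of log-incidence on transformed age.

A power law is linear in log-log coordinates (ln I vs ln t) and an
exponential is linear in semi-log coordinates (ln I vs t), so the whole
comparison machinery reduces to ordinary least squares of ln(incidence) on
one of two abscissae, plus a quadratic term to probe curvature, a
fractional-polynomial scan over abscissa exponents, and leave-one-out
cross-validation.  Natural logarithms are used internally throughout;
base-10 is a display matter only and does not change any R-squared.

The Gaussian log-likelihood reported with each fit uses the maximum
likelihood variance estimate rss/n, which makes likelihood-ratio Bayes
factors between two fits of the same response identical to
((1 - R2_0) / (1 - R2_1)) ** (n/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import RegistrySeries
from .errors import DomainError, UnderdeterminedError

__all__ = [
    "FitResult",
    "FracPolyResult",
    "fit_linear",
    "r2_difference",
    "supralinearity_check",
    "fracpoly_scan",
    "loo_r2",
    "as_points",
    "gaussian_loglik",
    "round_half_away",
]


def as_points(data):
    """Coerce input to (ages, incidences) arrays.

    Accepts a :class:`RegistrySeries`, a list of them (points stacked into
    one unweighted set, the "simple regression on non-pooled data" reading),
    or an ``(ages, incidences)`` pair.
    """
    if isinstance(data, RegistrySeries):
        return np.asarray(data.midpoints, float), np.asarray(data.incidences, float)
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], RegistrySeries):
        t = np.concatenate([np.asarray(s.midpoints, float) for s in data])
        i = np.concatenate([np.asarray(s.incidences, float) for s in data])
        return t, i
    t, i = data
    return np.asarray(t, float), np.asarray(i, float)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood with ML variance rss/n."""
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (report rounding convention)."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass
class FitResult:
    """One OLS fit of ln(incidence) on transformed age.

    ``coefficients`` is ``[intercept, slope]`` (degree 1) or
    ``[intercept, slope, quadratic]`` (degree 2).  On the log-log scale the
    slope estimates k - 1 of a power law; on the semi-log scale it estimates
    the exponential rate b (per year).  ``stderr`` are classical OLS
    standard errors; ``stderr_robust`` are HC3 heteroscedasticity-consistent
    ones (relevant because Poisson sampling noise on log-incidence shrinks
    with the case count of each bin).
    """

    scale: str
    degree: int
    coefficients: np.ndarray
    r_squared: float
    rss: float
    n: int
    loglik: float
    stderr: np.ndarray | None = None
    stderr_robust: np.ndarray | None = None
    response: np.ndarray = field(default=None, repr=False)

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def slope_ci(self, level: float = 0.95, robust: bool = True):
        """Two-sided slope confidence interval (t distribution, n - p df)."""
        from scipy import stats

        se = (self.stderr_robust if robust else self.stderr)[1]
        crit = stats.t.ppf(0.5 + level / 2, self.n - len(self.coefficients))
        return self.slope - crit * se, self.slope + crit * se

    def report_row(self) -> dict:
        row = {
            "scale": self.scale,
            "degree": self.degree,
            "intercept": float(self.coefficients[0]),
            "slope": float(self.coefficients[1]),
            "quadratic": float(self.coefficients[2]) if self.degree == 2 else None,
            "r_squared": self.r_squared,
            "rss": self.rss,
            "loglik": self.loglik,
            "n": self.n,
        }
        return row


@dataclass
class FracPolyResult:
    """Profile of the one-term fractional-polynomial scan ln I ~ t**x."""

    x_grid: np.ndarray
    loglik_per_x: np.ndarray
    x_opt: float
    coefficients: np.ndarray  # [intercept, slope] at x_opt

    def report_row(self) -> dict:
        return {
            "x_opt": float(self.x_opt),
            "intercept": float(self.coefficients[0]),
            "slope": float(self.coefficients[1]),
        }


def _abscissa(t, scale):
    if scale == "loglog":
        return np.log(t)
    if scale == "semilog":
        return t.copy()
    raise ValueError(f"unknown scale {scale!r}")


def _check_domain(t, incidence):
    if np.any(incidence <= 0):
        raise DomainError("incidence must be strictly positive on log scales; filter first")
    if np.any(t <= 0):
        raise DomainError("ages must be strictly positive")


def _ols(x_cols, y):
    """OLS with classical and HC3 standard errors; x_cols excludes intercept."""
    n = y.size
    X = np.column_stack([np.ones(n)] + list(x_cols))
    p = X.shape[1]
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    beta = XtXi @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    if n > p:
        se = np.sqrt(np.clip(np.diag(XtXi) * rss / (n - p), 0, None))
        h = np.clip(np.einsum("ij,jk,ik->i", X, XtXi, X), 0, 1 - 1e-12)
        meat = X.T @ (X * (resid**2 / (1 - h) ** 2)[:, None])
        se_robust = np.sqrt(np.clip(np.diag(XtXi @ meat @ XtXi), 0, None))
    else:
        se = se_robust = np.full(p, np.nan)
    return beta, rss, r2, se, se_robust


def fit_linear(data, scale: str, degree: int = 1) -> FitResult:
    """Fit ln(incidence) on {ln t | t} with an optional quadratic term.

    Requires at least ``degree + 2`` points and strictly positive incidences
    and ages.  Returns coefficients, R-squared, residual sum of squares and
    the ML Gaussian log-likelihood.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    t, incidence = as_points(data)
    _check_domain(t, incidence)
    n = t.size
    if n < degree + 2:
        raise UnderdeterminedError(f"need >= {degree + 2} points, got {n}")
    y = np.log(incidence)
    x = _abscissa(t, scale)
    cols = [x] if degree == 1 else [x, x**2]
    beta, rss, r2, se, se_rob = _ols(cols, y)
    return FitResult(
        scale=scale,
        degree=degree,
        coefficients=beta,
        r_squared=r2,
        rss=rss,
        n=n,
        loglik=gaussian_loglik(rss, n),
        stderr=se,
        stderr_robust=se_rob,
        response=y,
    )


def r2_difference(data, degree: int = 1) -> float:
    """Semi-log R-squared minus log-log R-squared; positive favors the exponential."""
    return (
        fit_linear(data, "semilog", degree).r_squared
        - fit_linear(data, "loglog", degree).r_squared
    )


def supralinearity_check(data, scale: str, linear_tol: float = 1e-8) -> str:
    """Classify curvature of ln(incidence) on the given scale.

    Returns ``"supralinear"``, ``"sublinear"`` or ``"linear"`` from the sign
    of the fitted quadratic coefficient.  The verdict is ``"linear"`` when
    the quadratic coefficient is below ``linear_tol`` in magnitude or when
    dropping it changes R-squared by less than 1e-4.
    """
    quad = fit_linear(data, scale, degree=2)
    lin = fit_linear(data, scale, degree=1)
    c2 = float(quad.coefficients[2])
    if abs(c2) < linear_tol or quad.r_squared - lin.r_squared < 1e-4:
        return "linear"
    return "supralinear" if c2 > 0 else "sublinear"


def default_x_grid():
    return np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def fracpoly_transform(t, x: float):
    """Box-Tidwell power transform: t**x, with ln t at x = 0."""
    return np.log(t) if x == 0 else t**x


def fracpoly_scan(data, x_grid=None) -> FracPolyResult:
    """Profile the fit of ln I = b1 * t**(x) + b2 over a grid of exponents.

    The maximizing exponent discriminates the two families: x_opt = 0 means
    power law (ln t is the x = 0 member of the transform family), x_opt = 1
    means exponential.  Ties are broken toward the smaller ``|x|`` with a
    warning.
    """
    t, incidence = as_points(data)
    _check_domain(t, incidence)
    if t.size < 4:
        raise UnderdeterminedError("fractional-polynomial scan needs >= 4 points")
    if x_grid is None:
        x_grid = default_x_grid()
    x_grid = np.asarray(x_grid, float)
    y = np.log(incidence)
    logliks = np.empty(x_grid.size)
    betas = []
    for j, ex in enumerate(x_grid):
        beta, rss, _, _, _ = _ols([fracpoly_transform(t, ex)], y)
        logliks[j] = gaussian_loglik(rss, t.size)
        betas.append(beta)
    best = np.max(logliks)
    tied = np.flatnonzero(np.isclose(logliks, best, rtol=0.0, atol=1e-10))
    if tied.size > 1:
        warnings.warn(
            f"fracpoly likelihood tie across x = {x_grid[tied]}; "
            "choosing the smallest |x|",
            stacklevel=2,
        )
    pick = tied[np.argmin(np.abs(x_grid[tied]))]
    return FracPolyResult(
        x_grid=x_grid,
        loglik_per_x=logliks,
        x_opt=float(x_grid[pick]),
        coefficients=betas[pick],
    )


def loo_r2(data, scale: str, degree: int = 1) -> float:
    """Leave-one-out cross-validated R-squared.

    Each point is predicted by the fit on the remaining n - 1 points;
    returns ``1 - sum((y_i - pred_i)^2) / sum((y_i - mean(y))^2)``.  Can be
    negative when the model extrapolates poorly.  Needs ``degree + 2``
    points so that every leave-one-out subfit is determined (the minimal
    case makes each subfit exact).
    """
    t, incidence = as_points(data)
    _check_domain(t, incidence)
    n = t.size
    if n < degree + 2:
        raise UnderdeterminedError(f"LOO needs >= {degree + 2} points, got {n}")
    y = np.log(incidence)
    x = _abscissa(t, scale)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        cols = [x[mask]] if degree == 1 else [x[mask], x[mask] ** 2]
        beta, *_ = _ols(cols, y[mask])
        xi = [1.0, x[i]] if degree == 1 else [1.0, x[i], x[i] ** 2]
        preds[i] = np.dot(beta, xi)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float(((y - preds) ** 2).sum()) / tss
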