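"""Mixed-effects fits with registry-level random intercepts and slopes.

The hierarchical power-law and exponential models are

    ln(I) = b0 + b1*ln(t) + (u_r + v_r*ln(t)) + eps      (log-log scale)
    ln(I) = b0 + b1*t     + (u_r + v_r*t)     + eps      (semi-log scale)

with (u_r, v_r) jointly Gaussian across registries (unstructured 2x2
covariance) and eps iid Gaussian.  Estimation is full maximum likelihood
(never REML) so that log-likelihoods are comparable across the two abscissa
transforms; the likelihood-ratio Bayes factor between the two scales is
exp(loglik_semilog - loglik_loglog).  Data are never pooled here: the
registry structure is the point.

Estimation is delegated to ``statsmodels`` MixedLM.  The abscissa is
centered internally before fitting (random intercept/slope designs on raw
adult ages are badly conditioned); fixed effects are reported on the
original parametrization and the maximized likelihood is unaffected by the
reparametrization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import BayesComparison, grade_evidence
from .errors import UnderdeterminedError
from .fits import default_x_grid, fracpoly_transform

__all__ = ["HierFit", "fit_hier", "hier_bf", "hier_fracpoly", "hier_loo"]

#: Random-effect variances below this fraction of the fixed slope squared
#: (or of the response variance, for the intercept) flag a degenerate fit.
_DEGENERACY_TOL = 1e-6


@dataclass
class HierFit:
    """Maximum-likelihood mixed-model fit on one scale.

    ``r_squared`` is conditional: the squared correlation between observed
    and fitted ln(incidence) including the predicted random effects.
    """

    scale: str
    fixed: np.ndarray  # [beta0, beta1] on the original abscissa
    re_cov: np.ndarray  # 2x2 covariance of (u, v), original parametrization
    resid_var: float
    loglik: float
    r_squared: float
    n_points: int
    n_registries: int
    degenerate: bool = False
    converged: bool = True
    random_effects: dict = field(default_factory=dict, repr=False)

    @property
    def slope(self) -> float:
        return float(self.fixed[1])

    def report_block(self) -> dict:
        return {
            "scale": self.scale,
            "beta0": float(self.fixed[0]),
            "beta1": float(self.fixed[1]),
            "var_intercept": float(self.re_cov[0, 0]),
            "var_slope": float(self.re_cov[1, 1]),
            "cov_intercept_slope": float(self.re_cov[0, 1]),
            "resid_var": self.resid_var,
            "loglik": self.loglik,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "n_registries": self.n_registries,
            "degenerate": self.degenerate,
            "converged": self.converged,
        }


def _stack(series_list):
    t, y, groups = [], [], []
    for s in series_list:
        mids = np.asarray(s.midpoints, float)
        inc = np.asarray(s.incidences, float)
        if np.any(inc <= 0) or np.any(mids <= 0):
            raise ValueError(
                f"registry {s.registry_id!r} has non-positive entries; filter first"
            )
        t.append(mids)
        y.append(np.log(inc))
        groups.extend([s.registry_id] * mids.size)
    return np.concatenate(t), np.concatenate(y), np.asarray(groups)


def _abscissa(t, scale):
    if scale == "loglog":
        return np.log(t)
    if scale == "semilog":
        return np.asarray(t, float)
    # fractional-polynomial exponent passed as float
    return fracpoly_transform(np.asarray(t, float), float(scale))


def _fit_mixed(x, y, groups):
    """Centered MixedLM fit; returns results object and the centering shift."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    shift = float(np.mean(x))
    xc = x - shift
    X = np.column_stack([np.ones_like(xc), xc])
    model = MixedLM(y, X, groups=groups, exog_re=X)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=2000)
            except Exception:
                continue
            if best is None or res.llf > best.llf + 1e-10:
                best = res
            if getattr(res, "converged", False):
                if best.llf <= res.llf + 1e-8:
                    best = res if res.llf >= best.llf else best
                break
    if best is None:
        raise RuntimeError("mixed-model optimization failed on all optimizers")
    return best, shift


def _blups(res, X, groups):
    """Best linear unbiased predictors of (u, v) per group.

    Computed directly from the estimated covariance so that a singular
    (boundary) random-effects covariance degrades gracefully: the estimate
    is floored to the nearest positive-definite matrix instead of failing.
    """
    G = np.asarray(res.cov_re, float).copy()
    sigma2 = max(float(res.scale), 1e-300)
    eigvals = np.linalg.eigvalsh(G)
    floor = 1e-10 * max(sigma2, float(np.trace(G)), 1e-12)
    floored = eigvals[0] < floor
    if floored:
        G = G + (floor - min(eigvals[0], 0.0) + floor) * np.eye(2)
    resid = np.asarray(res.model.endog) - X @ res.fe_params
    out = {}
    for g in np.unique(groups):
        idx = groups == g
        Z = X[idx]
        V = Z @ G @ Z.T + sigma2 * np.eye(int(idx.sum()))
        out[g] = G @ Z.T @ np.linalg.solve(V, resid[idx])
    return out, floored


def fit_hier(series_list, scale: str) -> HierFit:
    """ML fit of the random-intercept/random-slope model on one scale.

    Needs at least two registries with three points each.  A random-effects
    covariance estimated at (or pushed to) the boundary is returned with a
    ``degenerate`` flag rather than an error, since between-registry
    variance can legitimately be zero.
    """
    series_list = list(series_list)
    if len(series_list) < 2:
        raise UnderdeterminedError("hierarchical fit needs >= 2 registries")
    if any(len(s.midpoints) < 3 for s in series_list):
        raise UnderdeterminedError("each registry needs >= 3 usable points")
    t, y, groups = _stack(series_list)
    x = _abscissa(t, scale)
    res, shift = _fit_mixed(x, y, groups)

    # back-transform fixed effects and RE covariance to the uncentered axis
    b0c, b1 = res.fe_params
    fixed = np.array([b0c - b1 * shift, b1])
    cov_c = np.asarray(res.cov_re)
    A = np.array([[1.0, -shift], [0.0, 1.0]])  # (u,v)_orig = A (u,v)_centered
    re_cov = A @ cov_c @ A.T

    Xc = np.column_stack([np.ones_like(x), x - shift])
    blups, floored = _blups(res, Xc, groups)
    fitted = Xc @ res.fe_params + np.array(
        [Xc[i] @ blups[groups[i]] for i in range(y.size)]
    )
    vy = y - y.mean()
    vf = fitted - fitted.mean()
    denom = (vy @ vy) * (vf @ vf)
    r2 = float((vy @ vf) ** 2 / denom) if denom > 0 else 0.0

    slope_ref = max(b1**2, 1e-12)
    int_ref = max(float(np.var(y)), 1e-12)
    degenerate = (
        floored
        or cov_c[1, 1] <= _DEGENERACY_TOL * slope_ref
        or cov_c[0, 0] <= _DEGENERACY_TOL * int_ref
        or np.linalg.det(cov_c) <= 0
    )
    return HierFit(
        scale=str(scale),
        fixed=fixed,
        re_cov=re_cov,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        r_squared=r2,
        n_points=int(y.size),
        n_registries=int(np.unique(groups).size),
        degenerate=bool(degenerate),
        converged=bool(getattr(res, "converged", True)),
        random_effects={k: np.asarray(v) for k, v in blups.items()},
    )


def hier_bf(fit_semilog: HierFit, fit_loglog: HierFit) -> BayesComparison:
    """Likelihood-ratio BF10 of the hierarchical exponential over power law."""
    if fit_semilog.n_points != fit_loglog.n_points:
        raise ValueError("fits are on different data")
    bf10 = math.exp(fit_semilog.loglik - fit_loglog.loglik)
    comp = BayesComparison(
        bf10=bf10,
        method="ml_ratio",
        n=fit_semilog.n_points,
        prior_scale=None,
        degenerate=fit_semilog.degenerate or fit_loglog.degenerate,
    )
    comp.grade = grade_evidence(bf10) if bf10 != 1 else "none"
    return comp


def hier_fracpoly(series_list, x_grid=None):
    """Hierarchical fractional-polynomial profile over abscissa exponents.

    Fits the mixed model at each ``t**(x)`` (ln t at x = 0) and returns
    ``(x_grid, logliks, x_opt)``; exponents that fail to converge are
    recorded as NaN and excluded from the argmax with a warning.  Ties break
    toward the smaller ``|x|``.
    """
    if x_grid is None:
        x_grid = default_x_grid()
    x_grid = np.asarray(x_grid, float)
    logliks = np.full(x_grid.size, np.nan)
    for j, ex in enumerate(x_grid):
        try:
            logliks[j] = fit_hier(series_list, scale=ex).loglik
        except Exception as exc:  # pragma: no cover - rare optimizer failures
            warnings.warn(f"hier fracpoly failed at x={ex:g}: {exc}", stacklevel=2)
    if np.all(np.isnan(logliks)):
        raise RuntimeError("no exponent converged")
    best = np.nanmax(logliks)
    tied = np.flatnonzero(np.isclose(logliks, best, rtol=0.0, atol=1e-10))
    pick = tied[np.argmin(np.abs(x_grid[tied]))]
    return x_grid, logliks, float(x_grid[pick])


def hier_loo(series_list, scale: str) -> float:
    """Leave-one-out cross-validated R-squared of the hierarchical model.

    Each point is predicted from a refit without it, using the fixed effects
    plus the random effects re-predicted for its registry from that
    registry's remaining points.  If removal leaves a registry with fewer
    than two points, that point is predicted from fixed effects alone.
    """
    series_list = list(series_list)
    t, y, groups = _stack(series_list)
    x = _abscissa(t, scale)
    n = y.size
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        res, shift = _fit_mixed(x[mask], y[mask], groups[mask])
        xm = x[mask] - shift
        Xc = np.column_stack([np.ones_like(xm), xm])
        blups, _ = _blups(res, Xc, groups[mask])
        xi = x[i] - shift
        pred = res.fe_params[0] + res.fe_params[1] * xi
        gi = groups[i]
        remaining = np.count_nonzero(groups[mask] == gi)
        if remaining >= 2 and gi in blups:
            u, v = blups[gi]
            pred += u + v * xi
        preds[i] = pred
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float(((y - preds) ** 2).sum()) / tss
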