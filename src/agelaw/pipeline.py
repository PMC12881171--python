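"""Age-window diagnostics and end-to-end orchestration.

Both candidate curves (power law with k > 2, exponential with b > 0) have
strictly positive first and second derivatives, so the comparison is fair
only on an age range where the observed incidence actually accelerates.
:func:`acceleration_window` finds that range by walking second divided
differences of incidence from the youngest adult bin; incidence curves that
peak and decline (as neurodegenerative-disease incidence does at high ages)
are truncated before the comparison.  :func:`run_full_analysis` chains the
whole pipeline — filtering, pooling, window selection, linear/quadratic
fits, Bayes factors with prior robustness, fractional polynomials,
hierarchical models, LOO and the sensitivity scans — into one
machine-readable report.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import bayes, fits, hier, synth
from .data import RegistrySeries, filter_records, pool_registries, read_incidence_csv
from .errors import ConfigError, UnderdeterminedError

__all__ = [
    "AccelerationWindow",
    "SensitivityCurve",
    "acceleration_window",
    "sensitivity_scan",
    "run_full_analysis",
    "report_to_json",
]

SCHEMA_VERSION = 1


@dataclass
class AccelerationWindow:
    """Contiguous leading run of bins over which incidence accelerates."""

    included_bins: list
    upper_age_bound: float
    rule_trace: list  # (midpoint, second_difference, passed)
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.included_bins)


@dataclass
class SensitivityCurve:
    """Delta R^2 (semi-log minus log-log) as one window bound is varied."""

    mode: str  # vary_final_age | vary_initial_age
    bounds: list
    delta_r2: list
    n_points: list


def _median3(values):
    v = np.asarray(values, float)
    out = v.copy()
    for i in range(1, v.size - 1):
        out[i] = np.median(v[i - 1 : i + 2])
    return out


def acceleration_window(series: RegistrySeries, smooth: bool = False) -> AccelerationWindow:
    """Select the leading age window where incidence accelerates.

    Second divided differences of incidence (linear scale) against bin
    midpoints are computed; starting from the youngest bin the window is
    extended while the interior second difference is strictly positive and
    stops at the first violation.  The bound reported is the upper edge of
    the last included bin.  ``smooth`` applies a 3-point median filter
    before differencing (off by default; pooling is the intended smoother).
    """
    recs = [r for r in series if not r.bin.open_ended]
    if len(recs) < 4:
        raise UnderdeterminedError("acceleration window needs >= 4 bounded bins")
    m = np.array([r.bin.midpoint for r in recs])
    incidence = np.array([r.incidence for r in recs])
    if smooth:
        incidence = _median3(incidence)

    trace = []
    last_included = 1  # minimal leading window: first two bins
    violated = False
    any_positive = False
    for i in range(1, len(recs) - 1):
        d1 = (incidence[i] - incidence[i - 1]) / (m[i] - m[i - 1])
        d2 = (incidence[i + 1] - incidence[i]) / (m[i + 1] - m[i])
        second = 2.0 * (d2 - d1) / (m[i + 1] - m[i - 1])
        passed = (second > 0) and not violated
        trace.append((float(m[i]), float(second), bool(passed)))
        if passed:
            any_positive = True
            last_included = i + 1
        else:
            violated = True
    degenerate = not any_positive
    if degenerate:
        warnings.warn(
            "no strictly positive second difference; returning the minimal "
            "leading window",
            stacklevel=2,
        )
    included = recs[: last_included + 1]
    return AccelerationWindow(
        included_bins=included,
        upper_age_bound=float(included[-1].bin.upper),
        rule_trace=trace,
        degenerate=degenerate,
    )


def restrict_series(series: RegistrySeries, lower: float, upper: float) -> RegistrySeries:
    """Keep bins fully inside [lower, upper] (edges inclusive)."""
    kept = [
        r
        for r in series
        if not r.bin.open_ended and r.bin.lower >= lower and r.bin.upper <= upper
    ]
    return RegistrySeries(series.registry_id, kept, provenance=series.provenance)


def sensitivity_scan(
    series: RegistrySeries, mode: str, min_points: int = 4
) -> SensitivityCurve:
    """Delta R^2 over nested age windows.

    ``vary_final_age`` keeps the youngest bins and lowers the final age;
    ``vary_initial_age`` keeps the oldest bins and raises the starting age.
    Windows with fewer than ``min_points`` bins are excluded.
    """
    if mode not in ("vary_final_age", "vary_initial_age"):
        raise ValueError(f"unknown mode {mode!r}")
    recs = [r for r in series if not r.bin.open_ended]
    n = len(recs)
    bounds, deltas, ns = [], [], []
    if mode == "vary_final_age":
        windows = [(0, j) for j in range(min_points - 1, n)]
    else:
        windows = [(j, n - 1) for j in range(0, n - min_points + 1)]
    for lo, hi in windows:
        sub = RegistrySeries(series.registry_id, recs[lo : hi + 1])
        bound = recs[hi].bin.upper if mode == "vary_final_age" else recs[lo].bin.lower
        bounds.append(float(bound))
        deltas.append(fits.r2_difference(sub))
        ns.append(hi - lo + 1)
    if not bounds:
        warnings.warn("no admissible window for the sensitivity scan", stacklevel=2)
    order = np.argsort(bounds)
    return SensitivityCurve(
        mode=mode,
        bounds=[bounds[i] for i in order],
        delta_r2=[deltas[i] for i in order],
        n_points=[ns[i] for i in order],
    )


# ---------------------------------------------------------------------------
# full-pipeline orchestration


_CONFIG_KEYS = {
    "input",
    "truth",
    "pool",
    "window",
    "prior_scales",
    "fracpoly_grid",
    "hierarchical",
    "seed",
    "min_points",
    "adult_only",
}


def _validate_config(config: dict) -> list:
    problems = []
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    if ("input" in config) == ("truth" in config):
        problems.append("exactly one of 'input' (CSV path) or 'truth' must be given")
    if "truth" in config:
        t = config["truth"]
        if not isinstance(t, dict) or "family" not in t:
            problems.append("'truth' must be a mapping with a 'family' key")
        elif t["family"] not in ("exponential", "power_law", "multistep"):
            problems.append(f"unknown truth family {t['family']!r}")
    window = config.get("window", "auto")
    if window not in (None, "auto") and not (
        isinstance(window, (list, tuple))
        and len(window) == 2
        and all(isinstance(v, (int, float)) for v in window)
        and window[0] < window[1]
    ):
        problems.append("'window' must be 'auto', null, or [low, high] with low < high")
    scales = config.get("prior_scales", list(bayes.ROBUSTNESS_SCALES))
    if not all(isinstance(s, (int, float)) and s > 0 for s in scales):
        problems.append("'prior_scales' must all be positive numbers")
    grid = config.get("fracpoly_grid")
    if grid is not None and not (
        isinstance(grid, (list, tuple)) and len(grid) == 3 and grid[2] > 0 and grid[0] <= grid[1]
    ):
        problems.append("'fracpoly_grid' must be [min, max, step] with step > 0")
    if "seed" in config and not isinstance(config["seed"], int):
        problems.append("'seed' must be an integer")
    return problems


def _build_truth(tcfg: dict) -> synth.SyntheticTruth:
    family = tcfg["family"]
    if family == "exponential":
        return synth.SyntheticTruth(
            "exponential", a_e=tcfg.get("a_e", 0.032), b=tcfg.get("b", synth.DEFAULT_B)
        )
    if family == "power_law":
        return synth.SyntheticTruth(
            "power_law", a_m=tcfg.get("a_m", 2.0e-6), k=int(tcfg.get("k", synth.DEFAULT_K))
        )
    return synth.SyntheticTruth("multistep", step_rates=tuple(tcfg["step_rates"]))


def _simulate_input(config: dict):
    tcfg = dict(config["truth"])
    truth = _build_truth(tcfg)
    n_registries = int(tcfg.get("n_registries", 5))
    py = float(tcfg.get("person_years_per_bin", synth.DEFAULT_PERSON_YEARS))
    bins = synth.default_bins(
        *(tcfg.get("bins") or (25.0, 60.0, 5.0))
    )
    het = None
    if "heterogeneity" in tcfg:
        het = synth.HeterogeneitySpec(**tcfg["heterogeneity"])
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    series = [
        synth.simulate_registry(
            truth,
            bins,
            py,
            heterogeneity=het,
            seed=int(rng.integers(2**31 - 1)),
            registry_id=f"sim{j + 1}",
        )
        for j in range(n_registries)
    ]
    return series, truth


def run_full_analysis(config: dict) -> dict:
    """Run the whole comparison pipeline and return a JSON-ready report.

    The configuration names either an input CSV or a synthetic-truth block,
    plus pooling, age-window policy, prior scales, the fractional-polynomial
    grid and a seed.  All validation problems are reported together before
    any computation.  The same configuration and seed always produce the
    same report.
    """
    problems = _validate_config(config)
    if problems:
        raise ConfigError(problems)

    report: dict = {"schema_version": SCHEMA_VERSION, "config": _jsonify(config)}

    if "input" in config:
        series_list = read_incidence_csv(config["input"])
    else:
        series_list, truth = _simulate_input(config)
        report["truth"] = json.loads(json.dumps(_jsonify(
            {k: v for k, v in config["truth"].items()}
        )))

    adult_only = bool(config.get("adult_only", True))
    series_list = [filter_records(s, adult_only=adult_only) for s in series_list]
    series_list = [s for s in series_list if len(s)]
    if not series_list:
        raise ConfigError(["no usable records after filtering"])

    pool = bool(config.get("pool", True))
    have_counts = all(
        r.cases is not None and r.person_years is not None
        for s in series_list
        for r in s
    )
    pooled = (
        pool_registries(series_list)
        if (pool and len(series_list) > 1 and have_counts)
        else series_list[0]
        if len(series_list) == 1
        else None
    )
    reference = pooled if pooled is not None else series_list[0]

    # --- age window -------------------------------------------------------
    window = config.get("window", "auto")
    if window == "auto":
        win = acceleration_window(reference)
        lo = win.included_bins[0].bin.lower
        hi = win.upper_age_bound
        report["acceleration_window"] = {
            "upper_age_bound": hi,
            "n_bins": win.n_bins,
            "degenerate": win.degenerate,
            "rule_trace": [
                {"midpoint": mp, "second_difference": sd, "passed": ok}
                for mp, sd, ok in win.rule_trace
            ],
            "bound_convention": "upper bin edge",
        }
    elif window is None:
        lo, hi = -math.inf, math.inf
    else:
        lo, hi = float(window[0]), float(window[1])
    windowed = [restrict_series(s, lo, hi) for s in series_list]
    windowed = [s for s in windowed if len(s)]
    pooled_w = restrict_series(pooled, lo, hi) if pooled is not None else None
    points = pooled_w if pooled_w is not None else windowed

    # --- simple fits ------------------------------------------------------
    fit_block = {}
    for scale in ("loglog", "semilog"):
        for degree in (1, 2):
            f = fits.fit_linear(points, scale, degree)
            fit_block[f"{scale}_deg{degree}"] = f.report_row()
        fit_block[f"{scale}_curvature"] = fits.supralinearity_check(points, scale)
        fit_block[f"{scale}_loo_r2"] = fits.loo_r2(points, scale)
    fit_block["r2_difference"] = fits.r2_difference(points)
    report["fits"] = fit_block
    n_used = fit_block["loglog_deg1"]["n"]
    report["n_points"] = n_used

    # --- Bayes factors ----------------------------------------------------
    scales = [float(s) for s in config.get("prior_scales", bayes.ROBUSTNESS_SCALES)]
    robustness = bayes.prior_robustness(points, scales=scales)
    report["bayes"] = {
        "jzs": robustness[scales[0] if 0.354 not in scales else 0.354].report_block()
        if robustness
        else None,
        "robustness": [
            {"scale": (None if key == "ml_ratio" else key), **comp.report_block()}
            for key, comp in robustness.items()
        ],
        "ml_ratio": robustness["ml_ratio"].report_block(),
    }

    # --- fractional polynomials ------------------------------------------
    grid_cfg = config.get("fracpoly_grid")
    grid = (
        None
        if grid_cfg is None
        else np.round(np.arange(grid_cfg[0], grid_cfg[1] + 1e-9, grid_cfg[2]), 10)
    )
    fp = fits.fracpoly_scan(points, x_grid=grid)
    report["fracpoly"] = {
        "x_opt": fp.x_opt,
        "x_grid": [float(v) for v in fp.x_grid],
        "loglik_per_x": [float(v) for v in fp.loglik_per_x],
    }

    # --- hierarchical -----------------------------------------------------
    want_hier = config.get("hierarchical", "auto")
    do_hier = (len(windowed) >= 2) if want_hier == "auto" else bool(want_hier)
    if do_hier and len(windowed) >= 2:
        h1 = hier.fit_hier(windowed, "semilog")
        h0 = hier.fit_hier(windowed, "loglog")
        hb = hier.hier_bf(h1, h0)
        report["hierarchical"] = {
            "semilog": h1.report_block(),
            "loglog": h0.report_block(),
            "bf": hb.report_block(),
            "loo_r2_semilog": hier.hier_loo(windowed, "semilog"),
            "loo_r2_loglog": hier.hier_loo(windowed, "loglog"),
        }

    # --- sensitivity ------------------------------------------------------
    min_points = int(config.get("min_points", 4))
    sens_source = pooled if pooled is not None else series_list[0]
    report["sensitivity"] = {}
    for mode in ("vary_final_age", "vary_initial_age"):
        try:
            curve = sensitivity_scan(sens_source, mode, min_points=min_points)
        except UnderdeterminedError:
            continue
        report["sensitivity"][mode] = {
            "bounds": curve.bounds,
            "delta_r2": curve.delta_r2,
            "n_points": curve.n_points,
        }

    report["provenance"] = {
        "series": [
            {"registry": s.registry_id, "n_records": len(s), "note": s.provenance}
            for s in series_list
        ],
        "pooled": pooled.provenance if pooled is not None else None,
        "window": [None if not math.isfinite(lo) else lo, None if not math.isfinite(hi) else hi],
    }
    return _jsonify(report)


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _jsonify(obj):
    """Recursively convert to JSON-safe types, floats at 12 significant digits."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if math.isnan(x):
            return None
        return _round_sig(x)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic serialization (sorted keys, no timestamps)."""
    return json.dumps(report, sort_keys=True, indent=2)
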