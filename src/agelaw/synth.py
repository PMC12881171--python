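"""Synthetic multi-registry age-incidence data.

Three generating families are supported:

* ``exponential`` — I(t) = a_e * exp(b t), the Gompertz-like signature of a
  continuous damage-accumulation process;
* ``power_law`` — I(t) = a_m * t**(k-1), the low-age approximation of a
  k-step Armitage-Doll process;
* ``multistep`` — the exact hazard of a sequence of k irreversible steps
  with exponential waiting times (hypoexponential onset age; Erlang when
  all step rates are equal).

Registry sampling uses the rare-disease approximation: per bin, cases are
Poisson with mean ``I(midpoint)/1e5 * person_years`` and the at-risk pool is
not depleted.  The mechanistic cohort simulator
(:func:`simulate_multistep_cohort`) does deplete: subjects are censored at
onset and person-years at risk are accumulated exactly.

All randomness flows through a single ``numpy.random.default_rng(seed)``
stream per call; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.linalg import expm

from .data import AgeBin, IncidenceRecord, RegistrySeries
from .errors import DomainError

__all__ = [
    "SyntheticTruth",
    "HeterogeneitySpec",
    "expected_incidence",
    "simulate_registry",
    "simulate_multistep_cohort",
    "sample_onset_ages",
    "calibrated_amplitude",
    "truth_to_yaml",
    "truth_from_yaml",
    "default_bins",
    "DEFAULT_PERSON_YEARS",
    "DEFAULT_B",
    "DEFAULT_K",
]

#: Default per-year exponential acceleration (ALS-like).
DEFAULT_B = 0.117
#: Default number of steps for power-law / multistep truths.
DEFAULT_K = 5
#: Default person-years per 5-year bin per registry.
DEFAULT_PERSON_YEARS = 2.0e6


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating model for an age-incidence curve.

    Exactly the parameters of the declared family must be set:
    ``(a_e, b)`` for ``exponential``, ``(a_m, k)`` for ``power_law``,
    ``step_rates`` for ``multistep``.  Amplitudes are in incident cases per
    100,000 person-years; ``b`` is per year; step rates are per year.
    """

    family: str
    a_e: float | None = None
    b: float | None = None
    a_m: float | None = None
    k: int | None = None
    step_rates: tuple | None = None

    def __post_init__(self):
        if self.family == "exponential":
            if self.a_e is None or self.b is None or self.a_e <= 0 or self.b < 0:
                raise ValueError("exponential truth needs a_e > 0 and b >= 0")
            if self.a_m is not None or self.k is not None or self.step_rates is not None:
                raise ValueError("foreign parameters set on exponential truth")
        elif self.family == "power_law":
            if self.a_m is None or self.k is None or self.a_m <= 0 or self.k < 2:
                raise ValueError("power_law truth needs a_m > 0 and integer k >= 2")
            if self.a_e is not None or self.b is not None or self.step_rates is not None:
                raise ValueError("foreign parameters set on power_law truth")
        elif self.family == "multistep":
            if not self.step_rates or any(r <= 0 for r in self.step_rates):
                raise ValueError("multistep truth needs positive step_rates")
            object.__setattr__(self, "step_rates", tuple(float(r) for r in self.step_rates))
            if self.a_e is not None or self.b is not None or self.a_m is not None or self.k is not None:
                raise ValueError("foreign parameters set on multistep truth")
        else:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Between-registry variability of the log-incidence curve.

    ``intercept_sd`` acts on ln(incidence); ``slope_sd`` acts on the slope
    of the truth family's linear scale (b for exponential, k-1 for power
    law).  ``correlation`` couples the two offsets.
    """

    intercept_sd: float = 0.0
    slope_sd: float = 0.0
    correlation: float = 0.0

    def __post_init__(self):
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def _multistep_hazard(step_rates, t):
    """Exact hazard of a hypoexponential onset age, per year.

    The pre-onset process is a chain through k transient states with exit
    rates ``step_rates``; the hazard at t is rate_k * P(in last state at t)
    divided by P(not yet absorbed at t), evaluated with a matrix
    exponential so that repeated rates need no special casing.
    """
    rates = np.asarray(step_rates, dtype=float)
    k = rates.size
    Q = np.zeros((k, k))
    for i in range(k):
        Q[i, i] = -rates[i]
        if i + 1 < k:
            Q[i, i + 1] = rates[i]
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape)
    for idx, ti in np.ndenumerate(t):
        p = expm(Q * ti)[0]  # occupation probabilities of transient states
        surv = p.sum()
        out[idx] = rates[-1] * p[-1] / surv
    return out


def expected_incidence(truth: SyntheticTruth, t):
    """Noiseless incidence (per 100,000 person-years) at age(s) ``t`` > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("age must be positive")
    if truth.family == "exponential":
        out = truth.a_e * np.exp(truth.b * t)
    elif truth.family == "power_law":
        out = truth.a_m * t ** (truth.k - 1)
    else:
        out = _multistep_hazard(truth.step_rates, t) * 1e5
    return out if out.shape else float(out)


def calibrated_amplitude(
    truth: SyntheticTruth,
    bins,
    person_years_per_bin=DEFAULT_PERSON_YEARS,
    n_registries: int = 1,
    target_cases: float = 6000.0,
) -> float:
    """Amplitude rescaling so the design yields ``target_cases`` expected cases.

    Returns the factor by which the truth's amplitude (a_e or a_m) must be
    multiplied; for a unit-amplitude truth this is the calibrated amplitude
    itself.  Multistep truths have no free amplitude and are rejected.
    """
    if truth.family == "multistep":
        raise ValueError("multistep hazard has no free amplitude")
    mids = np.array([b.midpoint for b in bins])
    py = np.broadcast_to(np.asarray(person_years_per_bin, float), mids.shape)
    expected = expected_incidence(truth, mids) / 1e5 * py
    return target_cases / (expected.sum() * n_registries)


def default_bins(lower: float = 25.0, upper: float = 60.0, width: float = 5.0):
    """Adult 5-year bins [25,30), ..., [55,60); midpoints 27.5 ... 57.5."""
    edges = np.arange(lower, upper + 0.5 * width, width)
    return [AgeBin(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _registry_log_offsets(truth, heterogeneity, rng):
    """Draw (intercept, slope) offsets for one registry."""
    if heterogeneity is None:
        return 0.0, 0.0
    h = heterogeneity
    cov = np.array(
        [
            [h.intercept_sd**2, h.correlation * h.intercept_sd * h.slope_sd],
            [h.correlation * h.intercept_sd * h.slope_sd, h.slope_sd**2],
        ]
    )
    u, v = rng.multivariate_normal([0.0, 0.0], cov)
    if truth.family == "multistep" and v != 0.0:
        raise ValueError(
            "slope heterogeneity is undefined for the multistep family; "
            "set slope_sd = 0"
        )
    return u, v


def simulate_registry(
    truth: SyntheticTruth,
    bins,
    person_years_per_bin=DEFAULT_PERSON_YEARS,
    heterogeneity: HeterogeneitySpec | None = None,
    seed: int | None = None,
    registry_id: str = "sim",
) -> RegistrySeries:
    """Sample one registry's age-binned incidence under a generating truth.

    Per bin, ``cases ~ Poisson(I(midpoint)/1e5 * person_years)`` where the
    expected curve first receives this registry's random intercept/slope
    offsets on the family's linear scale.  Rare-disease approximation: the
    at-risk pool is not depleted.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    bins = list(bins)
    if any(b.open_ended for b in bins):
        raise ValueError("simulation bins must be bounded")
    mids = np.array([b.midpoint for b in bins])
    py = np.broadcast_to(np.asarray(person_years_per_bin, float), mids.shape)
    if np.any(py <= 0):
        raise ValueError("person-years must be positive")

    u, v = _registry_log_offsets(truth, heterogeneity, rng)
    log_i = np.log(expected_incidence(truth, mids))
    if truth.family == "exponential":
        log_i += u + v * mids
    elif truth.family == "power_law":
        log_i += u + v * np.log(mids)
    else:
        log_i += u
    mean_cases = np.exp(log_i) / 1e5 * py
    cases = rng.poisson(mean_cases)

    records = [
        IncidenceRecord(registry_id, b, c / p * 1e5, float(c), float(p))
        for b, c, p in zip(bins, cases, py)
    ]
    return RegistrySeries(
        registry_id,
        records,
        provenance="simulated registry\n" + truth_to_yaml(truth, heterogeneity, seed),
    )


def sample_onset_ages(step_rates, n_subjects: int, rng) -> np.ndarray:
    """Onset ages as sums of independent exponential waiting times (one per step)."""
    onset = np.zeros(n_subjects)
    for lam in step_rates:
        onset += rng.exponential(scale=1.0 / lam, size=n_subjects)
    return onset


def simulate_multistep_cohort(
    step_rates,
    n_subjects: int,
    bins,
    seed: int | None = None,
    registry_id: str = "cohort",
) -> RegistrySeries:
    """Mechanistic Armitage-Doll cohort: onset age = sum of k exponential waits.

    Each subject's onset age is drawn as the sum of independent exponential
    waiting times (one per step).  Binned incidence is onsets in the bin
    divided by exact person-years at risk in the bin, with subjects censored
    at onset; lifespan is otherwise unlimited.  Reproducible given ``seed``.
    """
    rates = [float(r) for r in step_rates]
    if not rates or any(r <= 0 for r in rates):
        raise ValueError("step rates must be positive")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    bins = list(bins)
    if any(b.open_ended for b in bins):
        raise ValueError("cohort bins must be bounded")

    rng = np.random.default_rng(seed)
    onset = sample_onset_ages(rates, n_subjects, rng)

    records = []
    for b in bins:
        in_bin = int(np.count_nonzero((onset >= b.lower) & (onset < b.upper)))
        at_risk = np.clip(np.minimum(onset, b.upper) - b.lower, 0.0, None)
        py = float(at_risk.sum())
        rate = in_bin / py * 1e5 if py > 0 else 0.0
        records.append(IncidenceRecord(registry_id, b, rate, float(in_bin), py if py > 0 else None))
    return RegistrySeries(
        registry_id,
        records,
        provenance=(
            "multistep cohort simulation\n"
            + yaml.safe_dump(
                {"step_rates": rates, "n_subjects": int(n_subjects), "seed": seed},
                sort_keys=False,
            )
        ),
    )


def truth_to_yaml(truth: SyntheticTruth, heterogeneity=None, seed=None) -> str:
    """Plain-text (YAML) echo of a generator configuration, for provenance."""
    cfg: dict = {"family": truth.family}
    if truth.family == "exponential":
        cfg.update(a_e=float(truth.a_e), b=float(truth.b))
    elif truth.family == "power_law":
        cfg.update(a_m=float(truth.a_m), k=int(truth.k))
    else:
        cfg.update(step_rates=[float(r) for r in truth.step_rates])
    if heterogeneity is not None:
        cfg["heterogeneity"] = {
            "intercept_sd": heterogeneity.intercept_sd,
            "slope_sd": heterogeneity.slope_sd,
            "correlation": heterogeneity.correlation,
        }
    if seed is not None:
        cfg["seed"] = int(seed)
    return yaml.safe_dump(cfg, sort_keys=False)


def truth_from_yaml(text: str) -> SyntheticTruth:
    """Inverse of :func:`truth_to_yaml` (generator parameters only)."""
    cfg = yaml.safe_load(text)
    family = cfg["family"]
    if family == "exponential":
        return SyntheticTruth("exponential", a_e=cfg["a_e"], b=cfg["b"])
    if family == "power_law":
        return SyntheticTruth("power_law", a_m=cfg["a_m"], k=int(cfg["k"]))
    return SyntheticTruth("multistep", step_rates=tuple(cfg["step_rates"]))
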