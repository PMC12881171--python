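"""Data model and I/O for age-binned incidence from disease registries.

The basic observation is one registry x age-bin cell: an incidence rate
expressed per 100,000 person-years, optionally backed by the raw case count
and person-years denominator.  Bins are closed-open intervals ``[lower,
upper)`` on exact age in years; the regression abscissa used throughout the
package is the bin midpoint ``(lower + upper) / 2``.  The highest age group
published by a registry is often open-ended ("80+"); such bins carry no
midpoint and are excluded before any curve is fitted.

CSV dialect
-----------
UTF-8, comma-separated, header required::

    registry,age_lower,age_upper,incidence[,cases,person_years]

An open upper bound is encoded as an empty ``age_upper`` field or ``"+"``.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import IncompatibleGridError, MissingWeightsError, ParseError

__all__ = [
    "AgeBin",
    "IncidenceRecord",
    "RegistrySeries",
    "read_incidence_csv",
    "write_incidence_csv",
    "filter_records",
    "pool_registries",
]

#: Relative tolerance used to reconcile a quoted rate with cases/person-years.
RATE_CONSISTENCY_RTOL = 0.02


@dataclass(frozen=True)
class AgeBin:
    """Closed-open age interval ``[lower, upper)`` in years.

    ``upper is None`` marks an open-ended bin (e.g. "80+"), which has no
    midpoint and cannot enter a regression.
    """

    lower: float
    upper: float | None = None

    def __post_init__(self):
        if self.lower < 0:
            raise ValueError(f"negative age bound: {self.lower}")
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"empty age bin [{self.lower}, {self.upper})")

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def midpoint(self) -> float:
        if self.upper is None:
            raise ValueError("open-ended bin has no midpoint")
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        if self.upper is None:
            raise ValueError("open-ended bin has no width")
        return self.upper - self.lower


@dataclass(frozen=True)
class IncidenceRecord:
    """One registry x age-bin observation.

    Parameters
    ----------
    registry_id : str
        Label of the source register.
    bin : AgeBin
        Age interval of the observation.
    incidence : float
        Rate per 100,000 person-years; must be non-negative.
    cases, person_years : float, optional
        Raw numerator/denominator.  When both are present the quoted rate
        must equal ``cases / person_years * 1e5`` within rounding tolerance.
    """

    registry_id: str
    bin: AgeBin
    incidence: float
    cases: float | None = None
    person_years: float | None = None

    def __post_init__(self):
        if self.incidence < 0:
            raise ValueError(f"negative incidence: {self.incidence}")
        if self.cases is not None and self.cases < 0:
            raise ValueError(f"negative case count: {self.cases}")
        if self.person_years is not None and self.person_years <= 0:
            raise ValueError(f"non-positive person-years: {self.person_years}")
        if self.cases is not None and self.person_years is not None:
            implied = self.cases / self.person_years * 1e5
            tol = RATE_CONSISTENCY_RTOL * max(implied, 1e-12) + 0.05
            if abs(implied - self.incidence) > tol:
                raise ValueError(
                    f"incidence {self.incidence} inconsistent with "
                    f"cases/person_years = {implied:.4g} per 100,000"
                )


@dataclass
class RegistrySeries:
    """Ordered incidence records for one registry (or a pooled pseudo-registry).

    Records are kept sorted by bin midpoint; open-ended bins sort last.
    """

    registry_id: str
    records: list[IncidenceRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        for rec in self.records:
            if rec.registry_id != self.registry_id:
                raise ValueError(
                    f"record registry {rec.registry_id!r} != series "
                    f"{self.registry_id!r}"
                )
        self.records = sorted(
            self.records,
            key=lambda r: (r.bin.open_ended, math.inf if r.bin.open_ended else r.bin.midpoint),
        )
        mids = [r.bin.midpoint for r in self.records if not r.bin.open_ended]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("bin midpoints are not strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def midpoints(self) -> list[float]:
        return [r.bin.midpoint for r in self.records if not r.bin.open_ended]

    @property
    def incidences(self) -> list[float]:
        return [r.incidence for r in self.records if not r.bin.open_ended]


def _parse_upper(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text in ("", "+", "inf", "open"):
        return None
    return float(text)


def read_incidence_csv(path) -> list[RegistrySeries]:
    """Read an incidence CSV into one :class:`RegistrySeries` per registry.

    Raises :class:`~agelaw.errors.ParseError` naming the offending row for
    malformed, non-numeric or invariant-violating input.
    """
    df = pd.read_csv(path, dtype={"registry": str, "age_upper": str})
    required = {"registry", "age_lower", "age_upper", "incidence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")

    by_registry: dict[str, list[IncidenceRecord]] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            bin_ = AgeBin(float(row["age_lower"]), _parse_upper(row["age_upper"]))
            cases = row.get("cases")
            py = row.get("person_years")
            rec = IncidenceRecord(
                registry_id=str(row["registry"]),
                bin=bin_,
                incidence=float(row["incidence"]),
                cases=None if cases is None or pd.isna(cases) else float(cases),
                person_years=None if py is None or pd.isna(py) else float(py),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"row {rowno}: {exc}") from exc
        by_registry.setdefault(rec.registry_id, []).append(rec)

    return [
        RegistrySeries(rid, recs, provenance=f"read from {path}")
        for rid, recs in by_registry.items()
    ]


def write_incidence_csv(series_list, path_or_buf) -> None:
    """Write series back to the same CSV dialect (round-trip safe)."""
    if isinstance(series_list, RegistrySeries):
        series_list = [series_list]
    rows = []
    for series in series_list:
        for rec in series:
            rows.append(
                {
                    "registry": rec.registry_id,
                    "age_lower": rec.bin.lower,
                    "age_upper": "" if rec.bin.open_ended else rec.bin.upper,
                    "incidence": rec.incidence,
                    "cases": "" if rec.cases is None else rec.cases,
                    "person_years": "" if rec.person_years is None else rec.person_years,
                }
            )
    df = pd.DataFrame(rows)
    if isinstance(path_or_buf, io.IOBase):
        df.to_csv(path_or_buf, index=False)
    else:
        df.to_csv(path_or_buf, index=False)


#: Youngest exact age admitted by the adult-only filter.  A bin whose lower
#: bound is below this (e.g. [15, 20)) straddles adulthood and is dropped.
ADULT_AGE = 18.0


def filter_records(
    series: RegistrySeries,
    adult_only: bool = True,
    drop_zero: bool = True,
    drop_unbounded: bool = True,
) -> RegistrySeries:
    """Apply the standard inclusion rules for curve comparison.

    Zero incidences become minus-infinity outliers on a log scale,
    open-ended bins have no usable age coordinate, and paediatric bins lie
    outside the adult ageing process under study; each rule can be toggled.
    Returns a new series; the input is untouched.  An empty result is legal
    and triggers a warning, not an error.
    """
    kept = []
    for rec in series:
        if drop_unbounded and rec.bin.open_ended:
            continue
        if adult_only and rec.bin.lower < ADULT_AGE:
            continue
        if drop_zero and rec.incidence == 0:
            continue
        kept.append(rec)
    if not kept:
        warnings.warn(
            f"all records of registry {series.registry_id!r} were filtered out",
            stacklevel=2,
        )
    return RegistrySeries(series.registry_id, kept, provenance=series.provenance)


def _grid_key(series: RegistrySeries):
    return tuple((r.bin.lower, r.bin.upper) for r in series)


def pool_registries(
    series_list: list[RegistrySeries],
    registry_id: str = "pooled",
    allow_person_years_weights: bool = False,
    allow_plain_mean: bool = False,
) -> RegistrySeries:
    """Pool several registries sharing one age-bin grid into a single series.

    The exact rule sums cases and person-years per bin and recomputes the
    rate.  When case counts are absent (graph-extracted rates), a
    person-years-weighted mean of rates may be enabled, or — with an explicit
    override — a plain mean, which is logged as approximate in the pooled
    series' provenance.
    """
    if not series_list:
        raise ValueError("nothing to pool")
    if len(series_list) == 1:
        s = series_list[0]
        return RegistrySeries(
            s.registry_id, list(s.records), provenance=s.provenance
        )

    grids = {_grid_key(s) for s in series_list}
    if len(grids) != 1:
        raise IncompatibleGridError(
            "registries do not share an identical age-bin grid: "
            + ", ".join(s.registry_id for s in series_list)
        )

    have_counts = all(
        r.cases is not None and r.person_years is not None
        for s in series_list
        for r in s
    )
    have_py = all(r.person_years is not None for s in series_list for r in s)

    pooled: list[IncidenceRecord] = []
    method = "summed counts"
    for recs in zip(*series_list):
        bin_ = recs[0].bin
        if have_counts:
            cases = sum(r.cases for r in recs)
            py = sum(r.person_years for r in recs)
            pooled.append(
                IncidenceRecord(registry_id, bin_, cases / py * 1e5, cases, py)
            )
        elif have_py and allow_person_years_weights:
            method = "person-years-weighted mean (approximate)"
            py = sum(r.person_years for r in recs)
            rate = sum(r.incidence * r.person_years for r in recs) / py
            pooled.append(IncidenceRecord(registry_id, bin_, rate, None, py))
        elif allow_plain_mean:
            method = "plain mean (approximate, override)"
            rate = sum(r.incidence for r in recs) / len(recs)
            pooled.append(IncidenceRecord(registry_id, bin_, rate))
        else:
            raise MissingWeightsError(
                "case counts absent; enable allow_person_years_weights or "
                "allow_plain_mean to pool extracted rates"
            )
    src = ", ".join(s.registry_id for s in series_list)
    return RegistrySeries(
        registry_id, pooled, provenance=f"pooled [{method}] from: {src}"
    )
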