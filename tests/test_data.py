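import io
import math

import pytest

from agelaw.data import (
    AgeBin,
    IncidenceRecord,
    RegistrySeries,
    filter_records,
    pool_registries,
    read_incidence_csv,
    write_incidence_csv,
)
from agelaw.errors import IncompatibleGridError, MissingWeightsError, ParseError


def make_csv(text):
    return io.StringIO(text.strip() + "\n")


HEADER = "registry,age_lower,age_upper,incidence,cases,person_years"


class TestAgeBin:
    def test_midpoint_and_width(self):
        b = AgeBin(25, 30)
        assert b.midpoint == 27.5
        assert b.width == 5
        assert not b.open_ended

    def test_open_ended_has_no_midpoint(self):
        b = AgeBin(80)
        assert b.open_ended
        with pytest.raises(ValueError):
            b.midpoint

    @pytest.mark.parametrize("lo,hi", [(30, 30), (30, 25), (-1, 5)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            AgeBin(lo, hi)


class TestIncidenceRecord:
    def test_rate_consistency_enforced(self):
        IncidenceRecord("r", AgeBin(25, 30), 5.0, cases=5, person_years=100_000)
        with pytest.raises(ValueError, match="inconsistent"):
            IncidenceRecord("r", AgeBin(25, 30), 9.0, cases=5, person_years=100_000)

    def test_negative_incidence_rejected(self):
        with pytest.raises(ValueError):
            IncidenceRecord("r", AgeBin(25, 30), -1.0)


class TestReadCsv:
    def test_two_registries_seven_bins(self):
        rows = [HEADER]
        for reg in ("A", "B"):
            for lo in range(25, 60, 5):
                rows.append(f"{reg},{lo},{lo + 5},{1.0 + lo / 10},,")
        series = read_incidence_csv(make_csv("\n".join(rows)))
        assert len(series) == 2
        assert all(len(s) == 7 for s in series)
        assert [s.registry_id for s in series] == ["A", "B"]

    def test_negative_incidence_names_row(self):
        text = f"{HEADER}\nA,25,30,-1,,"
        with pytest.raises(ParseError, match="row 2"):
            read_incidence_csv(make_csv(text))

    def test_non_numeric_field_names_row(self):
        text = f"{HEADER}\nA,25,30,2.0,,\nA,30,thirty-five,2.5,,"
        with pytest.raises(ParseError, match="row 3"):
            read_incidence_csv(make_csv(text))

    def test_open_upper_bound_flagged(self):
        text = "registry,age_lower,age_upper,incidence\nR1,80,+,3.2"
        (series,) = read_incidence_csv(make_csv(text))
        assert series.records[0].bin.open_ended

    def test_round_trip_preserves_fields(self):
        text = f"{HEADER}\nA,25,30,5.0,5,100000\nA,80,,3.25,,\nA,30,35,7.125,,"
        series = read_incidence_csv(make_csv(text))
        buf = io.StringIO()
        write_incidence_csv(series, buf)
        buf.seek(0)
        again = read_incidence_csv(buf)
        assert len(again) == len(series) == 1
        for a, b in zip(series[0], again[0]):
            assert a.bin == b.bin
            assert a.incidence == b.incidence
            assert a.cases == b.cases
            assert a.person_years == b.person_years


def series_with(records):
    return RegistrySeries("R", records)


class TestFilterRecords:
    def test_rules_and_count(self):
        # 10 records: one paediatric [15,20), one zero incidence, one
        # open-ended, seven admissible -> 7 survive
        recs = [IncidenceRecord("R", AgeBin(15, 20), 1.0)]
        for i in range(7):
            recs.append(IncidenceRecord("R", AgeBin(20 + 5 * i, 25 + 5 * i), 1.0 + i))
        recs.append(IncidenceRecord("R", AgeBin(57, 62), 0.0))
        recs.append(IncidenceRecord("R", AgeBin(80, None), 2.0))
        assert len(recs) == 10
        kept = filter_records(series_with(recs))
        assert len(kept) == 7

    def test_zero_incidence_removed(self):
        s = series_with([IncidenceRecord("R", AgeBin(40, 45), 0.0),
                         IncidenceRecord("R", AgeBin(45, 50), 2.0)])
        assert [r.incidence for r in filter_records(s)] == [2.0]

    def test_unbounded_removed(self):
        s = series_with([IncidenceRecord("R", AgeBin(80, None), 3.0),
                         IncidenceRecord("R", AgeBin(45, 50), 2.0)])
        assert all(not r.bin.open_ended for r in filter_records(s))

    def test_idempotent(self):
        recs = [IncidenceRecord("R", AgeBin(15, 20), 1.0),
                IncidenceRecord("R", AgeBin(40, 45), 0.0),
                IncidenceRecord("R", AgeBin(45, 50), 2.0)]
        once = filter_records(series_with(recs))
        twice = filter_records(once)
        assert [r.bin for r in once] == [r.bin for r in twice]
        assert [r.incidence for r in once] == [r.incidence for r in twice]

    def test_all_removed_warns_not_raises(self):
        s = series_with([IncidenceRecord("R", AgeBin(40, 45), 0.0)])
        with pytest.warns(UserWarning, match="filtered out"):
            out = filter_records(s)
        assert len(out) == 0

    def test_original_untouched(self):
        recs = [IncidenceRecord("R", AgeBin(40, 45), 0.0)]
        s = series_with(recs)
        with pytest.warns(UserWarning):
            filter_records(s)
        assert len(s) == 1


def counted(reg, lo, hi, cases, py):
    return IncidenceRecord(reg, AgeBin(lo, hi), cases / py * 1e5, cases, py)


class TestPoolRegistries:
    def test_counts_summed(self):
        a = RegistrySeries("A", [counted("A", 40, 45, 5, 100_000)])
        b = RegistrySeries("B", [counted("B", 40, 45, 15, 300_000)])
        pooled = pool_registries([a, b])
        assert pooled.records[0].incidence == pytest.approx(5.0)
        assert pooled.records[0].cases == 20
        assert pooled.records[0].person_years == 400_000

    def test_single_series_identity(self):
        a = RegistrySeries("A", [counted("A", 40, 45, 5, 100_000)])
        pooled = pool_registries([a])
        assert pooled.records[0].incidence == a.records[0].incidence
        assert pooled.registry_id == "A"

    def test_incompatible_grids_rejected(self):
        a = RegistrySeries("A", [counted("A", 40, 45, 5, 100_000)])
        b = RegistrySeries("B", [counted("B", 40, 50, 5, 100_000)])
        with pytest.raises(IncompatibleGridError):
            pool_registries([a, b])

    def test_pooling_copies_leaves_incidence_unchanged(self):
        recs = [counted("A", 40, 45, 8, 200_000), counted("A", 45, 50, 12, 200_000)]
        a = RegistrySeries("A", recs)
        copies = [RegistrySeries("A", list(recs)) for _ in range(4)]
        pooled = pool_registries(copies)
        for orig, got in zip(a, pooled):
            assert got.incidence == pytest.approx(orig.incidence)

    def test_missing_counts_requires_fallback(self):
        a = RegistrySeries("A", [IncidenceRecord("A", AgeBin(40, 45), 5.0)])
        b = RegistrySeries("B", [IncidenceRecord("B", AgeBin(40, 45), 7.0)])
        with pytest.raises(MissingWeightsError):
            pool_registries([a, b])
        pooled = pool_registries([a, b], allow_plain_mean=True)
        assert pooled.records[0].incidence == pytest.approx(6.0)
        assert "approximate" in pooled.provenance

    def test_person_years_weighted_fallback(self):
        a = RegistrySeries("A", [IncidenceRecord("A", AgeBin(40, 45), 4.0, person_years=100_000)])
        b = RegistrySeries("B", [IncidenceRecord("B", AgeBin(40, 45), 8.0, person_years=300_000)])
        pooled = pool_registries([a, b], allow_person_years_weights=True)
        assert pooled.records[0].incidence == pytest.approx(7.0)
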