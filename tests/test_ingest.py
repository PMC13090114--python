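"""CSV ingestion, validation, activity filtering and month partitioning."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermoreg.errors import ConfigError, DataError, ParseError
from thermoreg.ingest import (
    ActivityWindow,
    MicroclimateSeries,
    filter_activity,
    partition_by_month,
    read_assays,
    read_captures,
    read_microclimate,
    split_series_by_month,
    write_assays,
    write_captures,
    write_microclimate,
)

TOY = "site,timestamp,temperature\nA,2022-05-01T06:00:00,20.5\nA,2022-05-01T06:10:00,21.0\nA,2022-05-01T06:20:00,21.5\n"


def test_toy_csv_roundtrip_identity(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text(TOY)
    series = read_microclimate(p, source="recorded")
    assert len(series) == 1
    s = series[0]
    assert s.site_id == "A" and len(s) == 3
    np.testing.assert_allclose(s.temp, [20.5, 21.0, 21.5])
    out = tmp_path / "out.csv"
    write_microclimate(series, out)
    again = read_microclimate(out, source="recorded")[0]
    np.testing.assert_array_equal(again.temp, s.temp)
    assert (again.times == s.times).all()


def test_roundtrip_preserves_two_decimals(tmp_path):
    rng = np.random.default_rng(3)
    times = pd.date_range("2022-04-01", periods=50, freq="10min")
    temp = np.round(rng.uniform(-5, 45, size=50), 2)
    s = MicroclimateSeries(site_id="x", source="recorded", times=times, temp=temp)
    p = tmp_path / "rt.csv"
    write_microclimate([s], p)
    back = read_microclimate(p, source="recorded")[0]
    np.testing.assert_array_equal(back.temp, temp)


def test_duplicate_timestamp_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(
        "site,timestamp,temperature\n"
        "A,2022-05-01T06:00:00,20.5\nA,2022-05-01T06:00:00,21.0\n"
    )
    with pytest.raises(DataError, match="2022-05-01 06:00:00"):
        read_microclimate(p, source="recorded")


def test_interleaved_sites_sorted(tmp_path):
    rows = [
        ("B", "2022-05-01T07:00:00", 23.0),
        ("A", "2022-05-01T06:10:00", 21.0),
        ("B", "2022-05-01T06:30:00", 22.0),
        ("A", "2022-05-01T06:00:00", 20.0),
    ]
    p = tmp_path / "i.csv"
    p.write_text(
        "site,timestamp,temperature\n"
        + "\n".join(f"{s},{t},{v}" for s, t, v in rows)
    )
    series = read_microclimate(p, source="recorded")
    assert [s.site_id for s in series] == ["A", "B"]
    np.testing.assert_allclose(series[0].temp, [20.0, 21.0])  # hand-sorted
    np.testing.assert_allclose(series[1].temp, [22.0, 23.0])
    for s in series:
        assert s.times.is_monotonic_increasing


@pytest.mark.parametrize(
    "body,exc,match",
    [
        ("A,not-a-date,20.5\n", ParseError, "row 2"),
        ("A,2022-05-01T06:00:00,warm\n", ParseError, "row 2"),
    ],
)
def test_malformed_rows_named(tmp_path, body, exc, match):
    p = tmp_path / "bad.csv"
    p.write_text("site,timestamp,temperature\n" + body)
    with pytest.raises(exc, match=match):
        read_microclimate(p, source="recorded")


def test_shade_for_recorded_is_config_error(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text(TOY)
    with pytest.raises(ConfigError):
        read_microclimate(p, source="recorded", shade=0.5)


def test_plausibility_band_warns_then_errors(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text("site,timestamp,temperature\nA,2022-05-01T06:00:00,99.0\n")
    with pytest.warns(UserWarning, match="plausibility"):
        read_microclimate(p, source="recorded")
    with pytest.raises(DataError, match="plausibility"):
        read_microclimate(p, source="recorded", strict=True)


class TestFilterActivity:
    def test_full_day_retains_73_of_144(self, day_series):
        out = filter_activity(day_series, ActivityWindow())
        assert len(out) == 73  # [06:00, 18:00] inclusive at 10-min spacing

    def test_idempotent(self, day_series):
        once = filter_activity(day_series)
        twice = filter_activity(once)
        np.testing.assert_array_equal(once.temp, twice.temp)
        assert (once.times == twice.times).all()

    def test_inside_window_unchanged(self):
        times = pd.date_range("2022-06-15T10:00", periods=6, freq="10min")
        s = MicroclimateSeries(site_id="s", source="recorded", times=times,
                               temp=np.arange(6.0))
        out = filter_activity(s)
        np.testing.assert_array_equal(out.temp, s.temp)

    def test_night_only_gives_empty(self):
        times = pd.date_range("2022-06-15T22:00", periods=6, freq="10min")
        s = MicroclimateSeries(site_id="s", source="recorded", times=times,
                               temp=np.arange(6.0))
        assert len(filter_activity(s)) == 0

    def test_inverted_window_rejected(self):
        with pytest.raises(ConfigError):
            ActivityWindow(start=dt.time(18), end=dt.time(6))


class TestMonthPartition:
    def test_month_boundary_split(self):
        class R:
            def __init__(self, t):
                self.datetime = t

        recs = [R(dt.datetime(2022, 4, 30, 12)), R(dt.datetime(2022, 5, 1, 12))]
        parts = partition_by_month(recs)
        assert set(parts) == {(2022, 4), (2022, 5)}
        assert all(len(v) == 1 for v in parts.values())

    def test_empty_input(self):
        assert partition_by_month([]) == {}

    def test_season_span_inclusive_gives_eight_labels(self):
        days = pd.date_range("2022-04-01", "2022-11-01", freq="D")
        parts = partition_by_month(list(days), key=lambda t: t)
        assert len(parts) == 8  # Apr..Nov
        assert sum(len(v) for v in parts.values()) == len(days)

    def test_series_split_conserves_samples(self, day_series):
        times = pd.date_range("2022-04-25", periods=300, freq="6h")
        s = MicroclimateSeries(site_id="s", source="recorded", times=times,
                               temp=np.arange(300.0))
        parts = split_series_by_month(s)
        assert sum(len(p) for p in parts.values()) == 300


def test_capture_roundtrip_and_validation(tmp_path):
    from thermoreg.ingest import CaptureRecord

    rec = CaptureRecord(
        datetime=dt.datetime(2022, 6, 1, 10, 30), sex_class="male",
        svl_mm=46.2, mass_g=2.4, tb=33.1, ta=28.0, ts=31.5, sol=850.0,
        wind=1.2, substrate="rock",
    )
    p = tmp_path / "c.csv"
    write_captures([rec], p)
    back = read_captures(p)
    assert back[0].tb == pytest.approx(33.1)
    assert back[0].substrate == "rock"
    with pytest.raises(DataError):
        CaptureRecord(**{**rec.__dict__, "mass_g": -1.0})
    with pytest.raises(DataError):
        CaptureRecord(**{**rec.__dict__, "substrate": "sand"})


def test_assay_roundtrip_and_count_check(tmp_path):
    from thermoreg.ingest import AssayRecord

    rec = AssayRecord("i1", "female", tuple(30.0 + i for i in range(8)))
    p = tmp_path / "a.csv"
    write_assays([rec], p)
    back = read_assays(p)
    assert back[0].measurements == rec.measurements
    short = AssayRecord("i2", "male", (30.0, 31.0))
    write_assays([short], p)
    with pytest.raises(DataError, match="expected 8"):
        read_assays(p)
    assert read_assays(p, relax=True)[0].measurements == (30.0, 31.0)
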