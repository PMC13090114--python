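"""Reading, validation and time-filtering of the three study input types.

The pipeline consumes three kinds of records:

* microclimate temperature series from datalogger sites (``recorded``) or
  from a microclimate model run at discrete shade fractions (``modeled``);
* field capture records of individual lizards (body temperature plus the
  environmental and morphological covariates measured at capture);
* laboratory thermal-gradient assays (eight dorsal temperatures per
  individual at 15-min intervals).

All CSVs are comma-separated, dot-decimal, UTF-8 with a header row.
Timestamps are naive local time (the study design is single-site, so no
timezone arithmetic is performed).  Every reader accepts ``"-"`` for stdin.
"""

from __future__ import annotations

import datetime as dt
import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError

RECORDED = "recorded"
MODELED = "modeled"
SOURCES = (RECORDED, MODELED)
SEX_CLASSES = ("female", "male", "juvenile")
SUBSTRATES = ("soil", "grass", "rock")

#: Default plausibility band for temperatures (°C); a validation warning,
#: not a hard error, unless strict mode is requested.
DEFAULT_BAND = (-30.0, 70.0)

#: Temperatures round-trip through CSV at this precision, matching the
#: 0.01 °C instrument precision of the field thermometers.
TEMP_DECIMALS = 2


@dataclass(frozen=True)
class ActivityWindow:
    """Daily activity window of the animal; samples outside it are dropped.

    Both bounds are inclusive.  Default 06:00–18:00, the activity period
    used to filter datalogger recordings.
    """

    start: dt.time = dt.time(6, 0)
    end: dt.time = dt.time(18, 0)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigError(
                f"activity window start {self.start} must precede end {self.end}"
            )


@dataclass
class MicroclimateSeries:
    """A timestamped environmental temperature stream for one site.

    ``source`` is ``"recorded"`` (datalogger) or ``"modeled"`` (microclimate
    model); modeled series carry the shade fraction they were run at.
    """

    site_id: str
    source: str
    times: pd.DatetimeIndex
    temp: np.ndarray
    shade: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ConfigError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.source == RECORDED and self.shade is not None:
            raise ConfigError("shade fraction is only meaningful for modeled series")
        if self.source == MODELED:
            if self.shade is None:
                raise ConfigError("modeled series must carry a shade fraction")
            if not 0.0 <= float(self.shade) <= 1.0:
                raise ConfigError(f"shade fraction {self.shade} outside [0, 1]")
        self.times = pd.DatetimeIndex(self.times)
        self.temp = np.asarray(self.temp, dtype=float)
        if len(self.times) != len(self.temp):
            raise DataError(
                f"site {self.site_id}: {len(self.times)} timestamps vs {len(self.temp)} temperatures"
            )
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise DataError(f"site {self.site_id}: timestamps not increasing")
        dup = self.times.duplicated()
        if dup.any():
            raise DataError(
                f"site {self.site_id}: duplicate timestamp {self.times[dup][0]}"
            )
        if len(self.temp) and not np.all(np.isfinite(self.temp)):
            raise DataError(f"site {self.site_id}: non-finite temperature")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CaptureRecord:
    """One field capture: body temperature and covariates at the capture point."""

    datetime: dt.datetime
    sex_class: str
    svl_mm: float
    mass_g: float
    tb: float
    ta: float
    ts: float
    sol: float
    wind: float
    substrate: str

    def __post_init__(self) -> None:
        if self.sex_class not in SEX_CLASSES:
            raise DataError(f"sex_class {self.sex_class!r} not in {SEX_CLASSES}")
        if self.substrate not in SUBSTRATES:
            raise DataError(f"substrate {self.substrate!r} not in {SUBSTRATES}")
        for name in ("tb", "ta", "ts"):
            if not np.isfinite(getattr(self, name)):
                raise DataError(f"{name} is not finite")
        if not self.mass_g > 0:
            raise DataError(f"mass_g must be positive, got {self.mass_g}")
        if not self.svl_mm > 0:
            raise DataError(f"svl_mm must be positive, got {self.svl_mm}")


@dataclass(frozen=True)
class AssayRecord:
    """One thermal-gradient assay: 8 dorsal temperatures at 15-min intervals."""

    individual_id: str
    group: str
    measurements: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.group not in SEX_CLASSES:
            raise DataError(f"group {self.group!r} not in {SEX_CLASSES}")
        if not all(np.isfinite(m) for m in self.measurements):
            raise DataError(f"individual {self.individual_id}: non-finite measurement")


def _open_for_read(path):
    return sys.stdin if str(path) == "-" else path


def _open_for_write(path):
    return sys.stdout if str(path) == "-" else path


def check_plausibility(
    series: MicroclimateSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    strict: bool = False,
) -> None:
    """Warn (or raise in strict mode) on temperatures outside the band."""
    lo, hi = band
    bad = (series.temp < lo) | (series.temp > hi)
    if bad.any():
        msg = (
            f"site {series.site_id}: {int(bad.sum())} temperature(s) outside "
            f"plausibility band [{lo}, {hi}] °C, e.g. {series.temp[bad][0]:.2f}"
        )
        if strict:
            raise DataError(msg)
        warnings.warn(msg, stacklevel=2)


def read_microclimate(
    path,
    source: str,
    shade: float | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    strict: bool = False,
) -> list[MicroclimateSeries]:
    """Read a site,timestamp,temperature CSV into one series per site.

    Rows are sorted by time within each site; duplicate timestamps within a
    site are rejected.  ``shade`` must be given iff ``source == "modeled"``.
    """
    if source == RECORDED and shade is not None:
        raise ConfigError("shade fraction given for a recorded series")
    df = pd.read_csv(_open_for_read(path), dtype={"site": str})
    missing = {"site", "timestamp", "temperature"} - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)} in {path}")
    times = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ParseError(
            f"row {row + 2}: malformed timestamp {df['timestamp'].iloc[row]!r}"
        )
    temps = pd.to_numeric(df["temperature"], errors="coerce")
    if temps.isna().any():
        row = int(temps.isna().idxmax())
        raise ParseError(
            f"row {row + 2}: non-numeric temperature {df['temperature'].iloc[row]!r}"
        )
    out: list[MicroclimateSeries] = []
    for site, grp in df.assign(_t=times, _temp=temps).groupby("site", sort=True):
        grp = grp.sort_values("_t")
        t = pd.DatetimeIndex(grp["_t"])
        dup = t.duplicated()
        if dup.any():
            raise DataError(f"site {site}: duplicate timestamp {t[dup][0]}")
        s = MicroclimateSeries(
            site_id=str(site),
            source=source,
            times=t,
            temp=grp["_temp"].to_numpy(dtype=float),
            shade=shade,
        )
        check_plausibility(s, band=band, strict=strict)
        out.append(s)
    return out


def read_modeled_microclimate(
    path,
    band: tuple[float, float] = DEFAULT_BAND,
    strict: bool = False,
) -> list[MicroclimateSeries]:
    """Read modeled series from a CSV carrying a shade column.

    Expected columns: site,timestamp,temperature,shade; one series is
    produced per (site, shade) combination.
    """
    df = pd.read_csv(_open_for_read(path), dtype={"site": str})
    missing = {"site", "timestamp", "temperature", "shade"} - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)} in {path}")
    out: list[MicroclimateSeries] = []
    for (site, shade), grp in df.groupby(["site", "shade"], sort=True):
        times = pd.to_datetime(grp["timestamp"], format="ISO8601", errors="coerce")
        if times.isna().any():
            raise ParseError(f"site {site}: malformed timestamp in {path}")
        grp = grp.assign(_t=times).sort_values("_t")
        s = MicroclimateSeries(
            site_id=str(site),
            source=MODELED,
            times=pd.DatetimeIndex(grp["_t"]),
            temp=pd.to_numeric(grp["temperature"]).to_numpy(dtype=float),
            shade=float(shade),
        )
        check_plausibility(s, band=band, strict=strict)
        out.append(s)
    return out


def write_microclimate(series: Sequence[MicroclimateSeries], path) -> None:
    """Write series to CSV (site,timestamp,temperature[,shade]) at 0.01 °C."""
    frames = []
    any_modeled = any(s.source == MODELED for s in series)
    for s in series:
        d = {
            "site": s.site_id,
            "timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature": np.round(s.temp, TEMP_DECIMALS),
        }
        if any_modeled:
            d["shade"] = s.shade if s.shade is not None else ""
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(
        _open_for_write(path), index=False, float_format=f"%.{TEMP_DECIMALS}f"
    )


def filter_activity(
    series: MicroclimateSeries, window: ActivityWindow = ActivityWindow()
) -> MicroclimateSeries:
    """Keep only samples whose clock time falls within the window (inclusive)."""
    if len(series) == 0:
        return series
    idx = series.times.indexer_between_time(
        window.start, window.end, include_start=True, include_end=True
    )
    idx = np.sort(idx)
    return replace(series, times=series.times[idx], temp=series.temp[idx])


T = TypeVar("T")


def partition_by_month(
    items: Iterable[T],
    key: Callable[[T], dt.datetime] | None = None,
) -> dict[tuple[int, int], list[T]]:
    """Partition timestamped records into calendar-month bins.

    Keys are ``(year, month)`` tuples in chronological order; every record
    appears in exactly one bin.  ``key`` extracts the timestamp (default:
    the record's ``datetime`` attribute).
    """
    key = key or (lambda r: r.datetime)
    out: dict[tuple[int, int], list[T]] = {}
    for item in items:
        t = key(item)
        out.setdefault((t.year, t.month), []).append(item)
    return dict(sorted(out.items()))


def split_series_by_month(
    series: MicroclimateSeries,
) -> dict[tuple[int, int], MicroclimateSeries]:
    """Split one series into per-calendar-month sub-series."""
    out: dict[tuple[int, int], MicroclimateSeries] = {}
    if len(series) == 0:
        return out
    labels = list(zip(series.times.year, series.times.month))
    for ym in sorted(set(labels)):
        mask = np.array([l == ym for l in labels])
        out[ym] = replace(series, times=series.times[mask], temp=series.temp[mask])
    return out


def month_label(ym: tuple[int, int]) -> str:
    return f"{ym[0]:04d}-{ym[1]:02d}"


def read_captures(path) -> list[CaptureRecord]:
    """Read field capture records from CSV."""
    df = pd.read_csv(_open_for_read(path))
    required = {
        "datetime", "sex_class", "svl_mm", "mass_g",
        "tb", "ta", "ts", "sol", "wind", "substrate",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)} in {path}")
    times = pd.to_datetime(df["datetime"], format="ISO8601", errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ParseError(f"row {row + 2}: malformed datetime {df['datetime'].iloc[row]!r}")
    records = []
    for i, r in df.iterrows():
        records.append(
            CaptureRecord(
                datetime=times.iloc[i].to_pydatetime(),
                sex_class=str(r["sex_class"]),
                svl_mm=float(r["svl_mm"]),
                mass_g=float(r["mass_g"]),
                tb=float(r["tb"]),
                ta=float(r["ta"]),
                ts=float(r["ts"]),
                sol=float(r["sol"]),
                wind=float(r["wind"]),
                substrate=str(r["substrate"]),
            )
        )
    return records


def write_captures(records: Sequence[CaptureRecord], path) -> None:
    pd.DataFrame(
        {
            "datetime": [r.datetime.strftime("%Y-%m-%dT%H:%M:%S") for r in records],
            "sex_class": [r.sex_class for r in records],
            "svl_mm": [round(r.svl_mm, 2) for r in records],
            "mass_g": [round(r.mass_g, 2) for r in records],
            "tb": [round(r.tb, 2) for r in records],
            "ta": [round(r.ta, 2) for r in records],
            "ts": [round(r.ts, 2) for r in records],
            "sol": [round(r.sol, 1) for r in records],
            "wind": [round(r.wind, 2) for r in records],
            "substrate": [r.substrate for r in records],
        }
    ).to_csv(_open_for_write(path), index=False)


def read_assays(path, n_expected: int = 8, relax: bool = False) -> list[AssayRecord]:
    """Read thermal-gradient assays from a wide CSV (individual_id,group,t1..t8)."""
    df = pd.read_csv(_open_for_read(path), dtype={"individual_id": str})
    if {"individual_id", "group"} - set(df.columns):
        raise ParseError(f"missing id/group column in {path}")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    records = []
    for _, r in df.iterrows():
        meas = tuple(float(r[c]) for c in tcols if pd.notna(r[c]))
        if len(meas) != n_expected and not relax:
            raise DataError(
                f"individual {r['individual_id']}: expected {n_expected} "
                f"measurements, got {len(meas)}"
            )
        if not meas:
            raise DataError(f"individual {r['individual_id']}: no measurements")
        records.append(
            AssayRecord(
                individual_id=str(r["individual_id"]),
                group=str(r["group"]),
                measurements=meas,
            )
        )
    return records


def write_assays(records: Sequence[AssayRecord], path) -> None:
    n = max(len(r.measurements) for r in records)
    rows = []
    for r in records:
        row: dict = {"individual_id": r.individual_id, "group": r.group}
        for i in range(n):
            row[f"t{i + 1}"] = (
                round(r.measurements[i], 2) if i < len(r.measurements) else ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(_open_for_write(path), index=False)
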