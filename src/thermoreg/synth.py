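"""Synthetic study inputs with known ground truth.

Emulates the three study input types — datalogger microclimate series,
modeled shade-level series, thermal-gradient assays, and field captures —
with a known, tunable thermoregulation propensity ``p_reg`` as the ground
truth.  A capture regulates with probability ``p_reg`` (its body
temperature falls inside the set-point range, up to measurement noise) and
thermoconforms otherwise (its body temperature equals the operative
temperature at the capture point).  Under small regulation noise relative
to the range width this makes the expected Hertz index E ≈ p_reg, which is
what the recovery tests exploit.

The microclimate model is a deterministic seasonal + diurnal sinusoid per
site plus a per-site shade cooling, a per-site offset and AR(1) noise:

    T(t) = seasonal(t) + A·[cos(2π(h-15)/24) - cos(π/4)]
           - site_shade · shade_cooling_max · daylight(t) + offset + e(t)

where seasonal(t) interpolates the configured coldest/warmest midday means
half-sinusoidally across the season (so the configured values ARE the
midday means at the season's edges and peak), the diurnal term peaks at
15:00 and is calibrated to vanish at solar noon, and e(t) is a stationary
AR(1) process with autocorrelation ``ar1_rho`` and marginal SD
``noise_sd``.  Modeled shade series subtract a daylight-weighted cooling,
``s · shade_cooling_max · daylight(t)``, at hourly resolution.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophysics import OperativeSeries
from .errors import ConfigError, DataError
from .ingest import (
    MODELED,
    RECORDED,
    ActivityWindow,
    AssayRecord,
    CaptureRecord,
    MicroclimateSeries,
)
from .rng import rng_for
from .setpoints import SetpointRange

#: Default assay group sizes, matching the study's 23 gradient individuals.
DEFAULT_GROUP_SIZES = {"male": 13, "female": 3, "juvenile": 7}

#: Default per-site shade fractions for the recorded loggers, mirroring the
#: field placement under open soil (x2), grass, bush bottom, under rock and
#: tree bottom.  Cycled/truncated to n_sites.  Because the loggers sample
#: the same shade spectrum the microclimate model is run at, recorded and
#: modeled temperature pools agree at the habitat level, which is the
#: study condition the generator emulates.
DEFAULT_SITE_SHADES = (0.0, 0.0, 0.25, 0.5, 0.75, 1.0)

#: Field capture composition (male/female/juvenile) used to assign classes.
CAPTURE_CLASS_WEIGHTS = {"male": 76, "female": 16, "juvenile": 48}

SUBSTRATE_WEIGHTS = {"soil": 0.5, "grass": 0.3, "rock": 0.2}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic world; defaults emulate the study design.

    ``date_end`` is exclusive: the default span Apr 1 – Nov 1 yields 214
    full sampling days in months 4–10, one activity season.
    """

    seed: int = 0
    n_sites: int = 6
    date_start: dt.date = dt.date(2022, 4, 1)
    date_end: dt.date = dt.date(2022, 11, 1)
    sample_interval_min: int = 10
    diurnal_amplitude: float = 8.0
    seasonal_mean_range: tuple[float, float] = (15.0, 38.0)
    site_offsets: tuple[float, ...] | None = None  # drawn N(0, site_offset_sd²) if None
    site_offset_sd: float = 2.0
    site_shades: tuple[float, ...] | None = None  # default: DEFAULT_SITE_SHADES cycle
    ar1_rho: float = 0.8
    noise_sd: float = 1.5
    shade_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    shade_cooling_max: float = 10.0
    n_individuals: int = 23
    group_sizes: tuple[tuple[str, int], ...] = tuple(DEFAULT_GROUP_SIZES.items())
    tpref_mu: float = 32.10
    tpref_sd_between: float = 1.5
    tpref_sd_within: float = 1.0
    n_assay_measurements: int = 8
    n_captures: int = 140
    p_reg: float = 0.78
    tb_reg_noise_sd: float = 0.3
    mass_mu: float = 2.38
    mass_sd: float = 0.83
    svl_mu: float = 46.2
    svl_sd: float = 5.97

    def __post_init__(self) -> None:
        if self.date_end <= self.date_start:
            raise ConfigError("empty date span")
        if not 0.0 <= self.p_reg <= 1.0:
            raise ConfigError(f"p_reg must be in [0, 1], got {self.p_reg}")
        for name in ("diurnal_amplitude", "noise_sd", "site_offset_sd",
                     "tpref_sd_between", "tpref_sd_within", "tb_reg_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(not 0.0 <= s <= 1.0 for s in self.shade_levels):
            raise ConfigError("shade levels must lie in [0, 1]")
        if self.site_shades is not None and any(
            not 0.0 <= s <= 1.0 for s in self.site_shades
        ):
            raise ConfigError("site shades must lie in [0, 1]")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError(f"ar1_rho must be in (-1, 1), got {self.ar1_rho}")
        if sum(n for _, n in self.group_sizes) != self.n_individuals:
            raise ConfigError("group sizes must sum to n_individuals")


def _timestamps(config: SynthConfig, interval_min: int | None = None) -> pd.DatetimeIndex:
    interval = interval_min or config.sample_interval_min
    return pd.date_range(
        start=pd.Timestamp(config.date_start),
        end=pd.Timestamp(config.date_end),
        freq=f"{interval}min",
        inclusive="left",
    )


def _fractional_hour(times: pd.DatetimeIndex) -> np.ndarray:
    return times.hour.to_numpy() + times.minute.to_numpy() / 60.0


def deterministic_base(config: SynthConfig, times: pd.DatetimeIndex) -> np.ndarray:
    """Noise-free seasonal + diurnal temperature profile (closed form)."""
    t0 = pd.Timestamp(config.date_start)
    t1 = pd.Timestamp(config.date_end)
    frac = (times - t0).total_seconds() / (t1 - t0).total_seconds()
    cold, warm = config.seasonal_mean_range
    seasonal = cold + (warm - cold) * np.sin(np.pi * np.asarray(frac))
    h = _fractional_hour(times)
    a = config.diurnal_amplitude
    diurnal = a * np.cos(2.0 * np.pi * (h - 15.0) / 24.0)
    # calibrated so the profile equals `seasonal` exactly at solar noon
    return seasonal + diurnal - a * math.cos(math.pi / 4.0)


def daylight_factor(times: pd.DatetimeIndex) -> np.ndarray:
    """Daylight weight in [0, 1]: 0 at night, peaking at solar noon (12:00)."""
    h = _fractional_hour(times)
    return np.clip(np.sin(np.pi * (h - 6.0) / 12.0), 0.0, None)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for k in range(1, n):
        e[k] = rho * e[k - 1] + innov[k - 1]
    return e


def gen_base(config: SynthConfig, interval_min: int | None = None) -> MicroclimateSeries:
    """The deterministic site-free base series (no offset, no noise)."""
    times = _timestamps(config, interval_min)
    return MicroclimateSeries(
        site_id="base", source=RECORDED, times=times,
        temp=deterministic_base(config, times),
    )


def gen_microclimate(config: SynthConfig) -> list[MicroclimateSeries]:
    """Recorded datalogger series, one per site, at 10-min resolution."""
    times = _timestamps(config)
    if len(times) == 0:
        raise ConfigError("empty date span")
    base = deterministic_base(config, times)
    if config.site_offsets is not None:
        if len(config.site_offsets) != config.n_sites:
            raise ConfigError("site_offsets length must equal n_sites")
        offsets = np.asarray(config.site_offsets, dtype=float)
    else:
        offsets = rng_for(config.seed, "site_offsets").normal(
            0.0, config.site_offset_sd, size=config.n_sites
        )
    if config.site_shades is not None:
        if len(config.site_shades) != config.n_sites:
            raise ConfigError("site_shades length must equal n_sites")
        shades = np.asarray(config.site_shades, dtype=float)
    else:
        shades = np.array(
            [DEFAULT_SITE_SHADES[i % len(DEFAULT_SITE_SHADES)]
             for i in range(config.n_sites)]
        )
    cooling = config.shade_cooling_max * daylight_factor(times)
    out = []
    for i in range(config.n_sites):
        noise = _ar1(
            rng_for(config.seed, "microclimate", i),
            len(times), config.ar1_rho, config.noise_sd,
        )
        out.append(
            MicroclimateSeries(
                site_id=f"site{i + 1}",
                source=RECORDED,
                times=times,
                temp=base - shades[i] * cooling + offsets[i] + noise,
            )
        )
    return out


def gen_shaded(config: SynthConfig, base: MicroclimateSeries) -> list[MicroclimateSeries]:
    """Modeled series, one per shade level, at hourly resolution.

    ``modeled(t, s) = base(t) - s·shade_cooling_max·daylight(t)``; the
    zero-shade series equals the hourly resample of the base, and for any
    daylight instant temperature is non-increasing in shade.
    """
    on_hour = (base.times.minute == 0) & (base.times.second == 0)
    times = base.times[on_hour]
    temp = base.temp[np.asarray(on_hour)]
    cooling = config.shade_cooling_max * daylight_factor(times)
    return [
        MicroclimateSeries(
            site_id=base.site_id,
            source=MODELED,
            times=times,
            temp=temp - s * cooling,
            shade=float(s),
        )
        for s in config.shade_levels
    ]


def gen_assays(config: SynthConfig) -> list[AssayRecord]:
    """Thermal-gradient assays: individual means ~ N(tpref_mu, sd_between²),
    readings ~ N(individual mean, sd_within²); default groups 13m/3f/7j.
    """
    rng = rng_for(config.seed, "assays")
    records = []
    i = 0
    for group, n in config.group_sizes:
        for _ in range(n):
            i += 1
            mu = rng.normal(config.tpref_mu, config.tpref_sd_between)
            meas = rng.normal(mu, config.tpref_sd_within,
                              size=config.n_assay_measurements)
            records.append(
                AssayRecord(
                    individual_id=f"ind{i:02d}",
                    group=group,
                    measurements=tuple(float(m) for m in meas),
                )
            )
    return records


def _truncated_positive(rng: np.random.Generator, mu: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if v > 0:
            return float(v)
    raise DataError(f"could not draw a positive value from N({mu}, {sd}^2)")


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def gen_captures(
    config: SynthConfig,
    te_pool: list[OperativeSeries],
    setrange: SetpointRange,
    window: ActivityWindow = ActivityWindow(),
) -> list[CaptureRecord]:
    """Field captures with ground-truth regulation propensity ``p_reg``.

    Capture times are uniform over the activity-window samples of the
    operative pool.  With probability ``p_reg`` the capture regulates
    (T_b ~ Uniform over the set-point range, plus N(0, tb_reg_noise_sd²)
    measurement noise); otherwise it thermoconforms (T_b equals the
    operative temperature at that time and site, plus the same noise).
    Air/substrate temperatures are the operative temperature plus small
    offsets; morphology comes from the configured truncated normals.
    """
    if not te_pool:
        raise ConfigError("te_pool must be non-empty")
    rng = rng_for(config.seed, "captures")
    eligible: list[tuple[int, int]] = []
    for si, s in enumerate(te_pool):
        idx = s.times.indexer_between_time(
            window.start, window.end, include_start=True, include_end=True
        )
        eligible.extend((si, int(k)) for k in np.sort(idx))
    if not eligible:
        raise ConfigError("no operative samples inside the activity window")
    records = []
    for _ in range(config.n_captures):
        si, k = eligible[rng.integers(0, len(eligible))]
        series = te_pool[si]
        te = float(series.te[k])
        when = series.times[k].to_pydatetime()
        if rng.random() < config.p_reg:
            tb = rng.uniform(setrange.lower, setrange.upper)
        else:
            tb = te
        if config.tb_reg_noise_sd > 0:
            tb += rng.normal(0.0, config.tb_reg_noise_sd)
        sol = float(
            max(0.0, daylight_factor(pd.DatetimeIndex([when]))[0])
            * rng.uniform(400.0, 1000.0)
        )
        records.append(
            CaptureRecord(
                datetime=when,
                sex_class=_weighted_choice(rng, CAPTURE_CLASS_WEIGHTS),
                svl_mm=_truncated_positive(rng, config.svl_mu, config.svl_sd),
                mass_g=_truncated_positive(rng, config.mass_mu, config.mass_sd),
                tb=float(tb),
                ta=te + float(rng.normal(0.0, 1.0)),
                ts=te + float(rng.normal(0.0, 1.5)),
                sol=sol,
                wind=abs(float(rng.normal(1.0, 0.8))),
                substrate=_weighted_choice(rng, SUBSTRATE_WEIGHTS),
            )
        )
    return records
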