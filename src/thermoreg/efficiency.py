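"""Effectiveness of thermoregulation E with its two-step bootstrap.

The Hertz effectiveness index is

    E = 1 - d̄b / d̄e

where d̄b is the mean deviation of field body temperatures from the
set-point range and d̄e the mean deviation of available operative
temperatures.  E = 1 is a perfect regulator, E = 0 a thermoconformer;
negative values (body temperatures further from the set points than the
habitat average) are reported as-is, never clipped.

Because E is a single number, a two-step bootstrap builds its sampling
distribution: (1) draw ``n_points`` operative temperatures with
replacement from the environmental pool and compute E against the fixed
observed d̄b; (2) repeat ``n_reps`` times and take the equal-tailed
percentile interval of the resulting distribution.  Only the environmental
pool is resampled by default; ``resample_db=True`` additionally resamples
the body deviations (paired bootstrap) for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .biophysics import OperativeSeries
from .errors import ConfigError, DataError, UndefinedEfficiencyError
from .ingest import CaptureRecord, month_label, partition_by_month
from .rng import rng_for
from .setpoints import DeviationSet, SetpointRange, deviation, deviations

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling parameters for the two-step bootstrap (default 1000 x 1000)."""

    n_points: int = 1000
    n_reps: int = 1000
    seed: int | None = None
    ci_level: float = 0.95
    resample_db: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.n_reps < 1:
            raise ConfigError("n_points and n_reps must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")


@dataclass
class EfficiencyEstimate:
    """Point estimate, bootstrap distribution and CI of E for one stratum."""

    e_point: float
    db_mean: float
    de_mean: float
    distribution: np.ndarray
    ci: tuple[float, float]
    stratum: str
    source: str
    n_excluded: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.distribution))

    def summary(self) -> dict:
        return {
            "stratum": self.stratum,
            "source": self.source,
            "e_point": self.e_point,
            "e_median": self.median,
            "db_mean": self.db_mean,
            "de_mean": self.de_mean,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "n_reps": int(len(self.distribution)),
            "n_excluded": self.n_excluded,
        }


def efficiency_index(db_mean: float, de_mean: float) -> float:
    """E = 1 - d̄b/d̄e; undefined (error) when d̄e = 0."""
    if de_mean < 0 or db_mean < 0:
        raise DataError("mean deviations must be non-negative")
    if de_mean == 0.0:
        raise UndefinedEfficiencyError(
            "mean operative deviation is zero: every available temperature lies "
            "inside the set-point range, E is undefined"
        )
    return 1.0 - db_mean / de_mean


def bootstrap_efficiency(
    db_values: DeviationSet,
    te_pool,
    setrange: SetpointRange,
    config: BootstrapConfig = BootstrapConfig(),
    stratum: str = "all",
    source: str = "recorded",
    with_replacement: bool = True,
) -> EfficiencyEstimate:
    """Two-step bootstrap distribution of E for one stratum.

    ``te_pool`` is the pool of operative temperatures (°C) available to the
    animal in the stratum.  The point estimate uses the full pool; each
    replicate resamples ``n_points`` temperatures (with replacement unless
    ``with_replacement=False``, a diagnostic mode in which a replicate of
    the full pool size reproduces the deterministic point estimate).
    Replicates whose resampled d̄e is exactly zero leave E undefined and
    are excluded with a logged count.
    """
    pool = np.asarray(te_pool, dtype=float).ravel()
    if pool.size == 0:
        raise DataError("empty operative-temperature pool")
    db_mean = db_values.mean
    de_full = float(np.mean(deviation(pool, setrange)))
    e_point = efficiency_index(db_mean, de_full)

    rng = rng_for(config.seed, "efficiency", stratum, source)
    if with_replacement:
        idx = rng.integers(0, pool.size, size=(config.n_reps, config.n_points))
        samples = pool[idx]
    else:
        if config.n_points > pool.size:
            raise ConfigError(
                f"cannot draw {config.n_points} points without replacement "
                f"from a pool of {pool.size}"
            )
        samples = np.stack(
            [rng.choice(pool, size=config.n_points, replace=False)
             for _ in range(config.n_reps)]
        )
    de_rep = deviation(samples, setrange).mean(axis=1)

    if config.resample_db:
        db_idx = rng.integers(0, len(db_values), size=(config.n_reps, len(db_values)))
        db_rep = db_values.values[db_idx].mean(axis=1)
    else:
        db_rep = np.full(config.n_reps, db_mean)

    ok = de_rep > 0.0
    n_excluded = int(config.n_reps - ok.sum())
    if n_excluded:
        logger.warning(
            "stratum %s/%s: %d replicate(s) with zero mean operative deviation "
            "excluded", stratum, source, n_excluded,
        )
    if not ok.any():
        raise UndefinedEfficiencyError(
            f"stratum {stratum}/{source}: all bootstrap replicates degenerate"
        )
    dist = 1.0 - db_rep[ok] / de_rep[ok]
    tail = (1.0 - config.ci_level) / 2.0
    lo, hi = np.quantile(dist, [tail, 1.0 - tail])
    return EfficiencyEstimate(
        e_point=e_point,
        db_mean=db_mean,
        de_mean=de_full,
        distribution=dist,
        ci=(float(lo), float(hi)),
        stratum=stratum,
        source=source,
        n_excluded=n_excluded,
    )


def pool_te(series_list: list[OperativeSeries]) -> np.ndarray:
    """Concatenate the T_e samples of several operative series into one pool."""
    if not series_list:
        raise DataError("no operative series")
    return np.concatenate([s.te for s in series_list])


def monthly_efficiency(
    captures: list[CaptureRecord],
    te_series: list[OperativeSeries],
    setrange: SetpointRange,
    config: BootstrapConfig = BootstrapConfig(),
    source: str | None = None,
) -> list[EfficiencyEstimate]:
    """Per-calendar-month efficiency estimates.

    d_b pools the body temperatures of the month's captures; the operative
    pool is restricted to the month's T_e samples across all series.
    Months with captures but no operative samples are skipped with a logged
    warning.  Bootstrap streams are split per (month, source), so results
    do not depend on evaluation order.
    """
    if not captures or not te_series:
        raise DataError("captures and operative series must both be non-empty")
    source = source or te_series[0].source
    cap_by_month = partition_by_month(captures)
    te_by_month: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in te_series:
        for ym, sub in _split_te_by_month(s).items():
            te_by_month.setdefault(ym, []).append(sub)
    out: list[EfficiencyEstimate] = []
    for ym, caps in cap_by_month.items():
        label = month_label(ym)
        if ym not in te_by_month:
            logger.warning(
                "month %s: %d capture(s) but no operative samples; skipped",
                label, len(caps),
            )
            continue
        db = deviations([c.tb for c in caps], setrange, kind="db", stratum=label)
        pool = np.concatenate(te_by_month[ym])
        out.append(
            bootstrap_efficiency(
                db, pool, setrange, config, stratum=label, source=source
            )
        )
    return out


def _split_te_by_month(series: OperativeSeries) -> dict[tuple[int, int], np.ndarray]:
    out: dict[tuple[int, int], np.ndarray] = {}
    years, months = series.times.year, series.times.month
    for ym in sorted(set(zip(years, months))):
        mask = (years == ym[0]) & (months == ym[1])
        out[ym] = series.te[np.asarray(mask)]
    return out
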