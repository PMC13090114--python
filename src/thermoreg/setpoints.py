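"""Preferred temperatures, the set-point range, and deviations d_b / d_e.

The preferred temperature T_pref of an individual is the mean of its eight
thermal-gradient measurements.  The population set-point range T_set is the
central 50% interquartile interval (25th–75th percentile) of the individual
T_pref values.  The deviation of any temperature from the set-point range
is zero inside the range and the distance to the nearest bound outside it —
the standard Hertz convention.  Applied to field body temperatures this
yields d_b, applied to operative temperatures d_e.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .ingest import AssayRecord

QUANTILE_RULE = "linear"


@dataclass(frozen=True)
class SetpointRange:
    """Lower/upper preferred-temperature bounds (°C) with provenance."""

    lower: float
    upper: float
    n_individuals: int
    quantile_rule: str = QUANTILE_RULE

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise DataError(f"set-point range inverted: {self.lower} > {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class DeviationSet:
    """Non-negative deviations of a temperature sample from a set-point range."""

    values: np.ndarray
    kind: str  # "db" (body) or "de" (operative/environmental)
    stratum: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise DataError("empty deviation set")
        if np.any(self.values < 0):
            raise DataError("negative deviation")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def __len__(self) -> int:
        return len(self.values)


def tpref_of(assay: AssayRecord) -> float:
    """Individual preferred temperature: arithmetic mean of the assay readings."""
    if not assay.measurements:
        raise DataError(f"individual {assay.individual_id}: no measurements")
    return float(np.mean(assay.measurements))


def setpoint_range(
    tprefs: Sequence[float], lower_q: float = 0.25, upper_q: float = 0.75
) -> SetpointRange:
    """Central interquartile set-point range of individual T_pref values.

    Quantiles use linear interpolation between order statistics, the common
    default of the major statistical environments; the rule name travels
    with the result for provenance.
    """
    x = np.asarray(tprefs, dtype=float)
    if x.size < 2:
        raise DataError(f"need at least 2 individuals, got {x.size}")
    lo, hi = np.quantile(x, [lower_q, upper_q], method=QUANTILE_RULE)
    return SetpointRange(lower=float(lo), upper=float(hi), n_individuals=int(x.size))


def deviation(t, setrange: SetpointRange):
    """Deviation of temperature(s) from the range: 0 inside, distance to the
    nearest bound outside.  Accepts scalars or arrays; boundary values give
    exactly 0, and the map is continuous and 1-Lipschitz in t.
    """
    t = np.asarray(t, dtype=float)
    d = np.maximum(setrange.lower - t, np.maximum(t - setrange.upper, 0.0))
    return float(d) if d.ndim == 0 else d


def deviations(
    temps: Iterable[float], setrange: SetpointRange, kind: str, stratum: str = "all"
) -> DeviationSet:
    """Elementwise deviation of a temperature sample; preserves length."""
    t = np.asarray(list(temps) if not isinstance(temps, np.ndarray) else temps, float)
    if t.size == 0:
        raise DataError("empty temperature sample")
    return DeviationSet(values=deviation(t, setrange), kind=kind, stratum=stratum)
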