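import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermoreg.ingest import MicroclimateSeries
from thermoreg.setpoints import SetpointRange
from thermoreg.synth import SynthConfig


@pytest.fixture
def setrange():
    return SetpointRange(lower=31.0, upper=33.0, n_individuals=5)


@pytest.fixture
def day_series():
    """One full day at 10-min spacing (144 stamps, 00:00-23:50)."""
    times = pd.date_range("2022-06-15", periods=144, freq="10min")
    rng = np.random.default_rng(0)
    return MicroclimateSeries(
        site_id="s1", source="recorded", times=times,
        temp=25.0 + rng.normal(0, 2, size=144),
    )


@pytest.fixture
def small_synth():
    """A small, fast synthetic world configuration (two summer months)."""
    return SynthConfig(
        seed=11,
        n_sites=2,
        date_start=dt.date(2022, 5, 1),
        date_end=dt.date(2022, 7, 1),
        sample_interval_min=60,
        n_captures=200,
    )


def make_series(temps, start="2022-06-15T06:00", freq="10min", **kwargs):
    temps = np.asarray(temps, dtype=float)
    times = pd.date_range(start, periods=temps.size, freq=freq)
    defaults = dict(site_id="s1", source="recorded")
    defaults.update(kwargs)
    return MicroclimateSeries(times=times, temp=temps, **defaults)
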