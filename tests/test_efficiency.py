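"""Hertz effectiveness index and the two-step bootstrap."""

import numpy as np
import pytest

from thermoreg.efficiency import (
    BootstrapConfig,
    bootstrap_efficiency,
    efficiency_index,
    monthly_efficiency,
)
from thermoreg.errors import ConfigError, DataError, UndefinedEfficiencyError
from thermoreg.setpoints import DeviationSet, deviations


class TestIndex:
    def test_perfect_regulator(self):
        assert efficiency_index(0.0, 5.0) == 1.0

    def test_thermoconformer(self):
        assert efficiency_index(3.0, 3.0) == 0.0

    def test_direct_arithmetic(self):
        assert efficiency_index(1.1, 5.0) == pytest.approx(0.78)

    def test_zero_de_is_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            efficiency_index(0.5, 0.0)

    def test_negative_e_not_clipped(self):
        assert efficiency_index(6.0, 3.0) == pytest.approx(-1.0)

    def test_monotone_decreasing_in_db(self):
        es = [efficiency_index(db, 4.0) for db in np.linspace(0, 8, 20)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert all(e <= 1.0 for e in es)


@pytest.fixture
def db_zero(setrange):
    return deviations([32.0, 31.5, 32.5], setrange, kind="db")


class TestBootstrap:
    def test_degenerate_pool_far_outside(self, setrange, db_zero):
        pool = np.full(50, 45.0)  # every Te 12 degrees above the range
        est = bootstrap_efficiency(
            db_zero, pool, setrange, BootstrapConfig(n_points=20, n_reps=50, seed=0)
        )
        assert est.e_point == 1.0
        np.testing.assert_allclose(est.distribution, 1.0)
        assert est.ci == (1.0, 1.0)

    def test_same_seed_reproducible(self, setrange):
        rng = np.random.default_rng(0)
        pool = rng.uniform(15, 45, 300)
        db = deviations(rng.uniform(28, 36, 60), setrange, kind="db")
        cfg = BootstrapConfig(n_points=100, n_reps=100, seed=42)
        a = bootstrap_efficiency(db, pool, setrange, cfg)
        b = bootstrap_efficiency(db, pool, setrange, cfg)
        np.testing.assert_array_equal(a.distribution, b.distribution)
        assert a.ci == b.ci

    def test_different_seed_differs(self, setrange):
        rng = np.random.default_rng(0)
        pool = rng.uniform(15, 45, 300)
        db = deviations(rng.uniform(28, 36, 60), setrange, kind="db")
        a = bootstrap_efficiency(db, pool, setrange,
                                 BootstrapConfig(100, 100, seed=1))
        b = bootstrap_efficiency(db, pool, setrange,
                                 BootstrapConfig(100, 100, seed=2))
        assert not np.array_equal(a.distribution, b.distribution)

    def test_without_replacement_full_pool_collapses(self, setrange):
        """Diagnostic mode: full-pool draws without replacement must all
        equal the deterministic point estimate."""
        rng = np.random.default_rng(3)
        pool = rng.uniform(15, 45, 200)
        db = deviations(rng.uniform(28, 36, 40), setrange, kind="db")
        est = bootstrap_efficiency(
            db, pool, setrange,
            BootstrapConfig(n_points=200, n_reps=25, seed=0),
            with_replacement=False,
        )
        np.testing.assert_allclose(est.distribution, est.e_point, atol=1e-12)

    def test_without_replacement_overdraw_rejected(self, setrange, db_zero):
        with pytest.raises(ConfigError):
            bootstrap_efficiency(
                db_zero, np.arange(10.0), setrange,
                BootstrapConfig(n_points=11, n_reps=5, seed=0),
                with_replacement=False,
            )

    def test_ci_width_shrinks_with_n_points(self, setrange):
        rng = np.random.default_rng(4)
        pool = rng.uniform(15, 45, 20_000)
        db = deviations(rng.uniform(28, 36, 60), setrange, kind="db")
        widths = []
        for n_points in (100, 10_000):
            est = bootstrap_efficiency(
                db, pool, setrange, BootstrapConfig(n_points, 400, seed=5)
            )
            widths.append(est.ci[1] - est.ci[0])
        assert widths[1] < widths[0]

    def test_ci_brackets_median(self, setrange):
        rng = np.random.default_rng(6)
        pool = rng.uniform(15, 45, 500)
        db = deviations(rng.uniform(28, 36, 60), setrange, kind="db")
        est = bootstrap_efficiency(db, pool, setrange,
                                   BootstrapConfig(200, 200, seed=7))
        assert est.ci[0] <= est.median <= est.ci[1]
        assert est.e_point <= 1.0

    def test_empty_pool_rejected(self, setrange, db_zero):
        with pytest.raises(DataError):
            bootstrap_efficiency(db_zero, np.empty(0), setrange)

    def test_paired_bootstrap_resamples_db(self, setrange):
        rng = np.random.default_rng(8)
        pool = rng.uniform(15, 45, 300)
        db = deviations(rng.uniform(28, 40, 60), setrange, kind="db")
        fixed = bootstrap_efficiency(db, pool, setrange,
                                     BootstrapConfig(100, 200, seed=9))
        paired = bootstrap_efficiency(
            db, pool, setrange, BootstrapConfig(100, 200, seed=9, resample_db=True)
        )
        # resampling d_b adds a variance component
        assert paired.distribution.std() > fixed.distribution.std()


class TestMonthly:
    def _world(self, setrange):
        import pandas as pd
        from thermoreg.biophysics import OperativeSeries
        from thermoreg.ingest import CaptureRecord

        rng = np.random.default_rng(10)
        times = pd.date_range("2022-05-01T08:00", periods=400, freq="3h")
        te = OperativeSeries(site_id="s", source="recorded", times=times,
                             te=rng.uniform(15, 45, 400))
        caps = []
        for i in range(40):
            t = times[rng.integers(0, len(times))].to_pydatetime()
            caps.append(
                CaptureRecord(
                    datetime=t, sex_class="male", svl_mm=46.0, mass_g=2.4,
                    tb=float(rng.uniform(28, 36)), ta=25.0, ts=27.0,
                    sol=500.0, wind=1.0, substrate="soil",
                )
            )
        return caps, te

    def test_single_month_matches_direct_bootstrap(self, setrange):
        caps, te = self._world(setrange)
        may_caps = [c for c in caps if c.datetime.month == 5]
        mask = np.asarray(te.times.month == 5)
        import dataclasses
        te_may = dataclasses.replace(te, times=te.times[mask], te=te.te[mask])
        cfg = BootstrapConfig(50, 80, seed=11)
        ests = monthly_efficiency(may_caps, [te_may], setrange, cfg)
        assert len(ests) == 1
        db = deviations([c.tb for c in may_caps], setrange, kind="db",
                        stratum="2022-05")
        direct = bootstrap_efficiency(db, te_may.te, setrange, cfg,
                                      stratum="2022-05", source="recorded")
        np.testing.assert_array_equal(ests[0].distribution, direct.distribution)

    def test_monthly_count_and_strata(self, setrange):
        caps, te = self._world(setrange)
        ests = monthly_efficiency(caps, [te], setrange,
                                  BootstrapConfig(50, 60, seed=12))
        months_with_caps = {(c.datetime.year, c.datetime.month) for c in caps}
        assert len(ests) == len(months_with_caps)
        assert all(e.ci[0] <= e.median <= e.ci[1] for e in ests)

    def test_month_without_te_skipped_with_warning(self, setrange, caplog):
        caps, te = self._world(setrange)
        # restrict Te to May only; later-month captures must be skipped
        mask = np.asarray(te.times.month == 5)
        import dataclasses
        te_may = dataclasses.replace(te, times=te.times[mask], te=te.te[mask])
        with caplog.at_level("WARNING", logger="thermoreg.efficiency"):
            ests = monthly_efficiency(caps, [te_may], setrange,
                                      BootstrapConfig(50, 60, seed=13))
        assert len(ests) == 1
        assert "skipped" in caplog.text

    def test_empty_inputs_rejected(self, setrange):
        with pytest.raises(DataError):
            monthly_efficiency([], [], setrange)
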