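"""End-to-end orchestration: ingest → operative transform → set points →
efficiency → source comparisons → report.

Two distinct uses of the modeled shade series are easy to conflate and are
kept deliberately separate here:

* **temperature comparison** (recorded vs. modeled microclimate) uses the
  *shade-averaged* modeled series — the mean across the 0–100% shade
  levels at each timestamp — because that is the habitat-level summary a
  single logger approximates;
* **the d_e operative pool** for the modeled source pools *all* shade
  levels without averaging, because a free-ranging animal can choose its
  shade and every level is an available microhabitat.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import OperativeSeries, ThermalParams, operative_series
from .efficiency import (
    BootstrapConfig,
    EfficiencyEstimate,
    bootstrap_efficiency,
    monthly_efficiency,
    pool_te,
)
from .errors import ConfigError, DataError
from .ingest import (
    MODELED,
    RECORDED,
    ActivityWindow,
    MicroclimateSeries,
    filter_activity,
    month_label,
    partition_by_month,
    read_assays,
    read_captures,
    read_microclimate,
    read_modeled_microclimate,
    split_series_by_month,
)
from .rng import rng_for
from .setpoints import SetpointRange, deviations, setpoint_range, tpref_of
from .stats import TestResult, TostResult, kruskal_wallis, tost, welch_t
from .synth import (
    SynthConfig,
    gen_assays,
    gen_base,
    gen_captures,
    gen_microclimate,
    gen_shaded,
)

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE_MARGIN = 1.0  # °C, microclimate equivalence
DEFAULT_EFFICIENCY_MARGIN = 0.05  # absolute on the E scale ("5%")


@dataclass
class ComparisonRow:
    """Recorded vs. modeled microclimate for one month (or overall)."""

    month: str
    recorded_mean: float | None
    modeled_mean: float | None
    abs_diff: float | None
    tost: TostResult | None
    n_recorded: int
    n_modeled: int

    @property
    def missing(self) -> str | None:
        if self.n_recorded == 0:
            return "recorded"
        if self.n_modeled == 0:
            return "modeled"
        return None

    def to_dict(self) -> dict:
        return {
            "month": self.month,
            "recorded_mean": self.recorded_mean,
            "modeled_mean": self.modeled_mean,
            "abs_diff": self.abs_diff,
            "n_recorded": self.n_recorded,
            "n_modeled": self.n_modeled,
            "missing": self.missing,
            "tost": _tost_dict(self.tost),
        }


def _tost_dict(t: TostResult | None) -> dict | None:
    if t is None:
        return None
    return {
        "margin": t.margin,
        "mean_diff": t.mean_diff,
        "p_lower": t.p_lower,
        "p_upper": t.p_upper,
        "alpha": t.alpha,
        "equivalent": t.equivalent,
        "degenerate": t.degenerate,
    }


def _test_dict(t: TestResult | None) -> dict | None:
    if t is None:
        return None
    return {
        "test": t.test,
        "statistic": t.statistic,
        "df": t.df,
        "p": t.p,
        "degenerate": t.degenerate,
    }


def shade_average(modeled: list[MicroclimateSeries]) -> MicroclimateSeries:
    """Mean across shade levels at each common timestamp."""
    if not modeled:
        raise DataError("no modeled series to average")
    cols = {
        f"{s.site_id}/{s.shade}": pd.Series(s.temp, index=s.times) for s in modeled
    }
    df = pd.concat(cols, axis=1, join="inner")
    if df.empty:
        raise DataError("modeled series share no common timestamps")
    return MicroclimateSeries(
        site_id=modeled[0].site_id,
        source=RECORDED,  # shade-free summary stream; no shade attribute
        times=df.index,
        temp=df.mean(axis=1).to_numpy(),
    )


def _month_pools(series_list: list[MicroclimateSeries]) -> dict[tuple[int, int], np.ndarray]:
    pools: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in series_list:
        for ym, sub in split_series_by_month(s).items():
            pools.setdefault(ym, []).append(sub.temp)
    return {ym: np.concatenate(v) for ym, v in sorted(pools.items())}


def compare_sources(
    recorded: list[MicroclimateSeries],
    modeled: list[MicroclimateSeries],
    margin: float = DEFAULT_TEMPERATURE_MARGIN,
    overall_mode: str = "pooled_means",
) -> list[ComparisonRow]:
    """Monthly + overall comparison of recorded vs. shade-averaged modeled
    microclimate temperatures, with a TOST verdict at the given margin.

    ``overall_mode`` selects how the overall ``abs_diff`` is computed:
    ``"pooled_means"`` (absolute difference of the two pooled means,
    default) or ``"mean_monthly"`` (mean of the monthly absolute
    differences).  Activity filtering is assumed done by the caller.
    """
    if not recorded or not modeled:
        raise DataError("both sources must be non-empty")
    if overall_mode not in ("pooled_means", "mean_monthly"):
        raise ConfigError(f"unknown overall_mode {overall_mode!r}")
    avg = shade_average(modeled)
    rec_pools = _month_pools(recorded)
    mod_pools = _month_pools([avg])
    rows: list[ComparisonRow] = []
    for ym in sorted(set(rec_pools) | set(mod_pools)):
        rec = rec_pools.get(ym, np.empty(0))
        mod = mod_pools.get(ym, np.empty(0))
        label = month_label(ym)
        if rec.size == 0 or mod.size == 0:
            logger.warning("month %s present in only one source", label)
            rows.append(
                ComparisonRow(
                    month=label,
                    recorded_mean=float(rec.mean()) if rec.size else None,
                    modeled_mean=float(mod.mean()) if mod.size else None,
                    abs_diff=None,
                    tost=None,
                    n_recorded=int(rec.size),
                    n_modeled=int(mod.size),
                )
            )
            continue
        rows.append(
            ComparisonRow(
                month=label,
                recorded_mean=float(rec.mean()),
                modeled_mean=float(mod.mean()),
                abs_diff=float(abs(rec.mean() - mod.mean())),
                tost=tost(rec, mod, margin=margin),
                n_recorded=int(rec.size),
                n_modeled=int(mod.size),
            )
        )
    rec_all = np.concatenate(list(rec_pools.values()))
    mod_all = np.concatenate(list(mod_pools.values()))
    if overall_mode == "pooled_means":
        overall_diff = float(abs(rec_all.mean() - mod_all.mean()))
    else:
        monthly = [r.abs_diff for r in rows if r.abs_diff is not None]
        overall_diff = float(np.mean(monthly)) if monthly else None
    rows.append(
        ComparisonRow(
            month="overall",
            recorded_mean=float(rec_all.mean()),
            modeled_mean=float(mod_all.mean()),
            abs_diff=overall_diff,
            tost=tost(rec_all, mod_all, margin=margin),
            n_recorded=int(rec_all.size),
            n_modeled=int(mod_all.size),
        )
    )
    return rows


def compare_efficiency(
    est_a: EfficiencyEstimate,
    est_b: EfficiencyEstimate,
    margin: float = DEFAULT_EFFICIENCY_MARGIN,
) -> tuple[TostResult, TestResult]:
    """Welch t and TOST (absolute margin on the E scale) between the two
    bootstrap E distributions."""
    if len(est_a.distribution) == 0 or len(est_b.distribution) == 0:
        raise DataError("empty bootstrap distribution")
    return (
        tost(est_a.distribution, est_b.distribution, margin=margin),
        welch_t(est_a.distribution, est_b.distribution),
    )


@dataclass
class RunReport:
    """Everything a run produced, serialisable to JSON deterministically."""

    config: dict
    seed: int | None
    setrange: SetpointRange
    tpref_mean: float
    tpref_group_test: TestResult
    estimates: list[EfficiencyEstimate]
    comparisons: list[ComparisonRow]
    efficiency_tests: list[dict]
    ground_truth: dict | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "setpoint_range": {
                "lower": self.setrange.lower,
                "upper": self.setrange.upper,
                "n_individuals": self.setrange.n_individuals,
                "quantile_rule": self.setrange.quantile_rule,
            },
            "tpref_mean": self.tpref_mean,
            "tpref_group_test": _test_dict(self.tpref_group_test),
            "efficiency": [e.summary() for e in self.estimates],
            "temperature_comparison": [r.to_dict() for r in self.comparisons],
            "efficiency_comparison": self.efficiency_tests,
            "ground_truth": self.ground_truth,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"configuration in {path} is not a mapping")
    return cfg


def _parse_window(cfg: dict) -> ActivityWindow:
    w = cfg.get("window")
    if not w:
        return ActivityWindow()
    return ActivityWindow(
        start=dt.time.fromisoformat(str(w["start"])),
        end=dt.time.fromisoformat(str(w["end"])),
    )


def filter_te_activity(
    series: OperativeSeries, window: ActivityWindow
) -> OperativeSeries:
    idx = series.times.indexer_between_time(
        window.start, window.end, include_start=True, include_end=True
    )
    idx = np.sort(idx)
    return OperativeSeries(
        site_id=series.site_id,
        source=series.source,
        times=series.times[idx],
        te=series.te[idx],
        shade=series.shade,
    )


def _simulate_world(cfg: dict, seed: int | None):
    overrides = dict(cfg.get("simulate") or {})
    modeled_mode = overrides.pop("modeled_mode", "shaded")
    if seed is not None:
        overrides.setdefault("seed", seed)
    if "date_start" in overrides:
        overrides["date_start"] = dt.date.fromisoformat(str(overrides["date_start"]))
    if "date_end" in overrides:
        overrides["date_end"] = dt.date.fromisoformat(str(overrides["date_end"]))
    for tup in ("shade_levels", "seasonal_mean_range", "site_offsets"):
        if tup in overrides and overrides[tup] is not None:
            overrides[tup] = tuple(overrides[tup])
    if "group_sizes" in overrides:
        overrides["group_sizes"] = tuple(
            (str(k), int(v)) for k, v in dict(overrides["group_sizes"]).items()
        )
    scfg = SynthConfig(**overrides)
    recorded = gen_microclimate(scfg)
    if modeled_mode == "shaded":
        modeled = gen_shaded(scfg, gen_base(scfg))
    elif modeled_mode == "noisy_copy":
        # Modeled source emulated as a lightly perturbed copy of each
        # recorded logger (hourly), labelled with a nominal shade of 0.
        modeled = []
        rng = rng_for(scfg.seed, "noisy_copy")
        for s in recorded:
            on_hour = (s.times.minute == 0) & (s.times.second == 0)
            times = s.times[on_hour]
            temp = s.temp[np.asarray(on_hour)] + rng.normal(0.0, 0.3, size=len(times))
            modeled.append(
                MicroclimateSeries(
                    site_id=s.site_id, source=MODELED, times=times,
                    temp=temp, shade=0.0,
                )
            )
    else:
        raise ConfigError(f"unknown modeled_mode {modeled_mode!r}")
    return scfg, recorded, modeled


def run_pipeline(config: dict | str) -> RunReport:
    """Execute the full analysis from a configuration mapping or file path.

    The configuration either requests simulation (``simulate:`` with
    synthetic-world overrides) or names input files (``inputs:`` with
    ``recorded``, ``modeled``, ``captures``, ``assays`` paths).  Fully
    reproducible from config + seed.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    seed = cfg.get("seed")
    window = _parse_window(cfg)
    params = ThermalParams(**(cfg.get("thermal") or {}))
    bs_kwargs = dict(cfg.get("bootstrap") or {})
    bs_kwargs.setdefault("seed", seed)
    bs = BootstrapConfig(**bs_kwargs)
    t_margin = float(cfg.get("temperature_margin", DEFAULT_TEMPERATURE_MARGIN))
    e_margin = float(cfg.get("efficiency_margin", DEFAULT_EFFICIENCY_MARGIN))
    overall_mode = cfg.get("overall_mode", "pooled_means")

    ground_truth = None
    if "simulate" in cfg:
        scfg, recorded, modeled = _simulate_world(cfg, seed)
        assays = gen_assays(scfg)
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        recorded = read_microclimate(inp["recorded"], source=RECORDED)
        modeled = read_modeled_microclimate(inp["modeled"])
        assays = read_assays(inp["assays"])
    else:
        raise ConfigError("config must contain either 'simulate' or 'inputs'")
    logger.info("ingest: %d recorded series, %d modeled series, %d assays",
                len(recorded), len(modeled), len(assays))

    # Set points: Kruskal–Wallis gate across groups, then pooled T_pref.
    tprefs = [tpref_of(a) for a in assays]
    by_group: dict[str, list[float]] = {}
    for a, tp in zip(assays, tprefs):
        by_group.setdefault(a.group, []).append(tp)
    group_test = kruskal_wallis(list(by_group.values()))
    if group_test.p < 0.05:
        logger.warning(
            "T_pref differs between groups (KW p=%.3f); pooling anyway as configured",
            group_test.p,
        )
    setrange = setpoint_range(tprefs)
    logger.info("set-point range: [%.2f, %.2f] °C from %d individuals",
                setrange.lower, setrange.upper, setrange.n_individuals)

    # Operative transform on full series, then restrict to activity hours.
    te_rec = [filter_te_activity(operative_series(s, params), window)
              for s in recorded]
    te_mod = [filter_te_activity(operative_series(s, params), window)
              for s in modeled]
    rec_f = [filter_activity(s, window) for s in recorded]
    mod_f = [filter_activity(s, window) for s in modeled]

    if "simulate" in cfg:
        captures = gen_captures(scfg, te_rec, setrange, window=window)
        ground_truth = {
            "p_reg": scfg.p_reg,
            "synth_seed": scfg.seed,
            "setpoint_lower": setrange.lower,
            "setpoint_upper": setrange.upper,
        }
    else:
        captures = read_captures(cfg["inputs"]["captures"])
    logger.info("captures: %d records", len(captures))
    if not captures:
        raise DataError("no capture records")

    db = deviations([c.tb for c in captures], setrange, kind="db")
    estimates: list[EfficiencyEstimate] = []
    for source, te_series in ((RECORDED, te_rec), (MODELED, te_mod)):
        estimates.append(
            bootstrap_efficiency(
                db, pool_te(te_series), setrange, bs,
                stratum="all", source=source,
            )
        )
        estimates.extend(
            monthly_efficiency(captures, te_series, setrange, bs, source=source)
        )

    comparisons = compare_sources(rec_f, mod_f, margin=t_margin,
                                  overall_mode=overall_mode)

    # Cross-source efficiency equivalence, overall and per month.
    eff_tests: list[dict] = []
    rec_by = {e.stratum: e for e in estimates if e.source == RECORDED}
    mod_by = {e.stratum: e for e in estimates if e.source == MODELED}
    for stratum in [s for s in rec_by if s in mod_by]:
        t_res, w_res = compare_efficiency(rec_by[stratum], mod_by[stratum],
                                          margin=e_margin)
        eff_tests.append(
            {"stratum": stratum, "tost": _tost_dict(t_res), "welch": _test_dict(w_res)}
        )

    snapshot = {k: v for k, v in cfg.items() if k != "inputs"}
    snapshot = json.loads(json.dumps(snapshot, default=str))
    return RunReport(
        config=snapshot,
        seed=seed,
        setrange=setrange,
        tpref_mean=float(np.mean(tprefs)),
        tpref_group_test=group_test,
        estimates=estimates,
        comparisons=comparisons,
        efficiency_tests=eff_tests,
        ground_truth=ground_truth,
    )


def report_table(report: RunReport) -> pd.DataFrame:
    """Human-readable monthly efficiency table (one row per stratum/source)."""
    return pd.DataFrame([e.summary() for e in report.estimates])
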