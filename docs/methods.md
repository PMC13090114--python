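# Methods

This note documents the models, parameters, numerical choices and known
limitations of `thermoreg`, in the spirit of the methods documentation of
mature simulation/statistics packages.

## Set points and deviations

An individual's preferred temperature T_pref is the arithmetic mean of its
8 gradient readings. The population set-point range T_set is the 25th–75th
percentile interval of the *individual* T_pref values (n individuals, not
n × 8 raw readings: T_pref is defined per individual; a raw-measurement
mode is available by passing raw means to `setpoint_range` directly).
Quantiles use linear interpolation between order statistics — the common
default of the major statistical environments — and the rule name is
recorded in the `SetpointRange` for provenance.

Deviation from T_set is 0 inside the range (bounds inclusive) and the
distance to the *nearest bound* outside it. "Distance to nearest bound" is
the standard convention for set-point deviations; since lower ≤ upper this
equals `max(lower − t, t − upper, 0)`, which is continuous and 1-Lipschitz
in t. The alternative reading (deviation from a point T_pref) is rejected
as inconsistent with a range-based set point.

## Operative temperature model

The operative-temperature transform is a first-order lumped-capacitance
model: a single thermal mass m·c coupled to the driver temperature through
a convective conductance h·A with the geometric allometry A = a·m^(2/3).

| parameter | default | units | meaning |
|---|---|---|---|
| `mass_g` | 2.4 | g | standard animal mass (field mean) |
| `specific_heat` | 3.5 | J·g⁻¹·K⁻¹ | wet-tissue specific heat |
| `area_coeff` | 10 | cm²·g^(−2/3) | surface allometry coefficient |
| `conv_coeff` | 15 | W·m⁻²·K⁻¹ | convective transfer coefficient |

These give τ = m·c/(h·A) ≈ 312 s at 2.4 g. Between samples the driver is
held constant and the update `Te ← D + (Te − D)·exp(−Δt/τ)` is the exact
solution of the ODE, so irregular sampling is handled per-step with no
integration error; activity-hour gaps simply appear as large Δt over which
the body equilibrates to the driver. The model deliberately has no
separate radiative/conductive/evaporative terms and no behaviour: the
logger (or modeled) temperature is taken to integrate the microhabitat.
All coefficients are exposed so users can calibrate the transform against
a full biophysical model if they have one; equivalence with any particular
external heat-budget implementation is not claimed.

## Efficiency and the two-step bootstrap

E = 1 − d̄_b/d̄_e. d̄_e = 0 (every available temperature inside T_set)
makes E undefined and raises an explicit error rather than guessing.
Negative E is reported unclipped. The bootstrap:

1. draw `n_points` (default 1000) operative temperatures with replacement
   from the stratum's pool, recompute d̄_e and E with the *fixed* observed
   d̄_b;
2. repeat `n_reps` (default 1000) times; the estimate interval is the
   equal-tailed percentile interval at `ci_level` (default 95%).

Holding d̄_b fixed mirrors a design in which only the environmental pool
is resampled; `resample_db=True` gives a paired bootstrap for sensitivity
analysis. Replicates with resampled d̄_e exactly 0 are excluded with a
logged count. A diagnostic mode (`with_replacement=False` with
`n_points = pool size`) collapses every replicate to the deterministic
full-pool E, which the tests use as a mechanical check. RNG streams are
split per (stratum, source) label via hashed spawn keys, so monthly
results are independent of evaluation order and reproducible under a
fixed seed.

For the modeled source the d_e pool concatenates **all** shade levels (a
free-ranging animal can choose its shade), whereas the recorded-vs-modeled
*temperature* comparison uses the **shade-averaged** modeled series (the
habitat-level summary a logger approximates). These two uses are easy to
conflate; they are intentionally different.

## Statistical tests

Welch's unequal-variance t is the base two-sample test everywhere,
including inside TOST; the variance assumption is deliberately the weaker
one. TOST tests the mean difference against −margin and +margin with two
one-sided Welch tests; equivalence requires both p < α (default 0.05).
Margins: 1 °C on microclimate temperatures, 0.05 absolute on the E scale
(E is a dimensionless fraction; "5%" is read as 0.05 absolute — a relative
reading is not well-defined for an index that can be 0 or negative).
Kruskal–Wallis uses midranks with tie correction and the χ² approximation
with k − 1 df; it gates the pooling of T_pref across sex/age groups
(pooled by default, with a logged warning if the gate rejects). No
multiple-testing correction is applied across months. Degenerate inputs
(two constant samples) short-circuit to conventional results (t = 0,
p = 1 when means agree) and are flagged.

These tests are standard procedures and are delegated to scipy
(`ttest_ind(equal_var=False)`, `kruskal`) and statsmodels (`ttost_ind`,
`usevar="unequal"`) behind the package's own result types; the test suite
pins them against hand-evaluated formulas on small samples and a
permutation oracle.

## Synthetic world

The generator emulates a single-population field study over one activity
season (default Apr 1 – Nov 1, end-exclusive: 214 sampling days, months
4–10) at 10-min logger resolution and hourly model resolution, filtered
downstream to 06:00–18:00 activity hours (both bounds inclusive).

Microclimate: `T(t) = seasonal(t) + diurnal(t) − site_shade·c_max·daylight(t)
+ site_offset + AR1(t)`. The seasonal term interpolates the configured
coldest/warmest midday means (15…38 °C) half-sinusoidally across the
season; the diurnal sinusoid (amplitude 8 °C) peaks at 15:00 and is
calibrated to vanish at solar noon, so the configured values are exactly
the open-ground midday means. Noise is a stationary AR(1) process
(ρ = 0.8, marginal SD 1.5 °C) — loggers show strong short-range
autocorrelation, so white noise would be unrealistic. Site offsets are
N(0, 2²) °C. Each logger site additionally carries a fixed shade fraction
(default cycle 0, 0, 0.25, 0.5, 0.75, 1 across sites), mirroring field
placements under open soil, grass, bush, rock and tree: loggers sample the
same shade spectrum the microclimate model is run at, which is what makes
recorded and modeled pools comparable at the habitat level — the condition
the source-comparison analyses are about. Modeled series subtract
`s·c_max·daylight(t)` (c_max = 10 °C at full shade and solar noon) from
the clean base at the five shade levels; shade is a daylight-weighted
subtractive cooling, with no radiation physics.

Assays: 23 individuals (13 male / 3 female / 7 juvenile), individual means
N(32.10, 1.5²) °C and readings N(mean, 1²) — the between/within split is
not separately identified by a pooled SD, so these defaults reproduce a
pooled spread of ≈ 3 °C while remaining configurable.

Captures: times uniform over activity-window operative samples; ground
truth is the regulation propensity `p_reg` (default 0.78, the efficiency
scale a field study of an effective heliothermic regulator reports). With
probability `p_reg` the capture's T_b is uniform over T_set (plus 0.3 °C
measurement noise), otherwise T_b equals the operative temperature at the
capture point (plus the same noise). Hence d̄_b ≈ (1 − p_reg)·E[d_e] and
the recovered E ≈ p_reg whenever the regulation noise is small relative to
the range width — the analytic link the recovery tests check, not an
assumption used elsewhere. Mass and SVL are positive-truncated normals
(2.38 ± 0.83 g, 46.2 ± 5.97 mm); air/substrate temperatures are the
operative temperature with small offsets.

What the generator does **not** emulate: humidity, wind and radiation
fields, logger dropout/gaps, within-season acclimatization, behavioural
microhabitat selection beyond the uniform-over-T_set regulator, and
weather (the seasonal/diurnal structure is smooth). Passing tests
therefore demonstrate that the pipeline recovers known structure of this
idealized world, not that any particular field dataset will show the same
values.

## Problem sizes

The test suite and the acceptance script scale the resampling down from
the 1000 × 1000 default to 150–300 points × reps, use 2000-capture worlds
for recovery sweeps (5 seeds per propensity), 200 two-month worlds for the
coverage experiment, and 2000 simulations for the TOST calibration check —
sizes chosen so the whole battery runs in well under a minute per
experiment on one CPU while keeping Monte-Carlo error comfortably inside
the asserted tolerances.

## Known limitations

- The lumped model is a one-state proxy; it captures mass-driven thermal
  inertia but not posture, evaporation or radiative load.
- Set-point quantiles from 23 individuals are themselves noisy; the
  package treats T_set as fixed when bootstrapping E (as the two-step
  design prescribes), so set-point uncertainty is not propagated.
- Monthly strata with captures but no operative samples are skipped with a
  warning rather than imputed.
- Temperature equivalence verdicts in synthetic worlds depend on the drawn
  site offsets; with 6 sites the offset mean has SD ≈ 0.8 °C, so
  individual worlds can fail a 1 °C TOST even though the construction is
  unbiased.
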