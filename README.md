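# thermoreg

Thermoregulatory-efficiency analysis for small ectotherms: from
microclimate temperature series and field capture records to operative
temperatures, preferred-temperature set-point ranges, bootstrap Hertz
effectiveness indices, and equivalence tests between field-recorded and
model-derived temperature sources.

## Who this is for

Thermal ecologists comparing how well a small lizard (or any small
dry-skinned ectotherm) keeps its body temperature inside its preferred
range, given the operative temperatures its habitat offers — and whether
indices computed from mechanistic microclimate models agree with those
computed from datalogger networks.

## The science in brief

**Set-point range.** Each individual's preferred temperature T_pref is the
mean of 8 thermal-gradient measurements taken at 15-min intervals; the
population set-point range T_set is the central 50% interquartile interval
of the individual T_pref values.

**Deviations.** The deviation of any temperature from T_set is 0 inside
the range and the distance to the nearest bound outside it. Applied to
field body temperatures T_b this gives d_b; applied to operative
temperatures T_e it gives d_e.

**Operative temperature.** T_e is the predicted body temperature of a
passive (non-regulating) standard animal. A first-order lumped-capacitance
model converts a driver series D(t) into T_e:

    dT_e/dt = (D − T_e)/τ,   τ = m·c / (h·A),   A = a·m^(2/3)

solved exactly per sampling step. For the 2.4 g standard animal τ ≈ 312 s.

**Effectiveness of thermoregulation (Hertz index).**

    E = 1 − d̄_b / d̄_e

E = 1 is a perfect regulator, E = 0 a thermoconformer; negative values are
reported as-is. Because E is a single number, a two-step bootstrap builds
its sampling distribution: each replicate draws 1000 operative temperature
points from the environmental pool (with replacement), recomputes d̄_e and
E against the fixed observed d̄_b; 1000 replicates give the distribution
and its equal-tailed 95% interval.

**Equivalence testing.** Recorded and modeled microclimate temperatures
are compared per month with a TOST procedure (two one-sided Welch tests)
at a 1 °C margin; efficiency distributions from the two sources are
compared at a 0.05 margin on the E scale. Group differences in T_pref are
gated with a Kruskal–Wallis test before pooling.

A synthetic-data module generates all three input types with diurnal and
seasonal thermal structure and a known regulation propensity `p_reg`, so
the whole pipeline is testable without field data: a synthetic capture
regulates (T_b uniform in T_set) with probability `p_reg` and
thermoconforms (T_b = T_e) otherwise, making the expected recovered E
approximately equal to `p_reg`.

## Worked example

Run a full synthetic season (6 logger sites, Apr–Oct, 10-min sampling,
140 captures, regulation propensity 0.78) and estimate E from both
temperature sources:

```python
from thermoreg.pipeline import run_pipeline

report = run_pipeline({
    "seed": 1,
    "simulate": {"p_reg": 0.78},
    "bootstrap": {"n_points": 300, "n_reps": 300},
})
for e in report.estimates:
    if e.stratum == "all":
        print(e.source, round(e.e_point, 3), [round(c, 3) for c in e.ci])
print("T_set:", round(report.setrange.lower, 2), "-",
      round(report.setrange.upper, 2), "°C")
```

prints

```
recorded 0.762 [0.736, 0.783]
modeled 0.8 [0.781, 0.815]
T_set: 31.55 - 33.05 °C
```

Both sources recover the ground-truth propensity 0.78 to within the
capture-sampling noise, and their bootstrap distributions are
TOST-equivalent at the 0.05 margin (`report.efficiency_tests`), even
though the raw pooled temperatures of the two sources differ by ~1.6 °C in
this world — the index depends on the set-point interval, not on point
temperature agreement.

The same analysis is scriptable from the shell:

```sh
thermoreg simulate --seed 1 --out world/
thermoreg run --config config.yaml --out report.json --table table.csv
```

with subcommands `simulate`, `operative`, `setpoints`, `efficiency`,
`equivalence` and `run` (exit codes: 0 ok, 2 data error, 3 config error).

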