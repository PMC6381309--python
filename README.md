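# critspeed

Analysis of 3-minute all-out running tests (AOT) for sport scientists and
coaches: estimate **critical speed (CS)**, the finite capacity for running
above it (**D′**), and the kinetics of the speed reserve, from a single
bout recorded with a 1 Hz GPS watch or a high-rate video digitisation —
for linear running and for 25/50 m shuttle running.

## The model

A 3-min all-out bout rises from rest to peak speed within seconds, then
decays exponentially toward a sustainable asymptote. `critspeed` fits the
piecewise bi-exponential speed–time curve

```
S(t) = S0 + Ad + Ag · (e^(−tc/τg) − e^(−t/τg))    t ≤ tc
S(t) = S0 + Ad · e^(−(t−tc)/τd)                    t > tc
```

where `S0` is the speed asymptote (the model's surrogate for CS), `Ad`
and `Ag` are the decay and growth amplitudes, `tc` is the time of peak
speed `Smax = S0 + Ad`, and `τg`, `τd` are the growth and decay time
constants. From a fitted curve it derives, in closed form:

- the **fatigue index** `FI% = 100·Ad/Smax` — the relative speed reserve;
- **S′**, the area under the curve above `S0` — the model-based analogue
  of D′ — plus total distance and the anaerobic distance fraction
  `100·S′/distance`;
- the classic window metrics: CS as the mean speed of the final 30 s and
  `D′ = (mean speed of the first 150 s − CS)·150`;
- predictions from the speed–time hyperbola: `speed = D′/t + CS` and
  `t_lim = (D − D′)/CS`.

Cohort tools cover the S′ regression on FI and τd, per-condition summary
tables, and agreement statistics (consistency ICC, typical error, CV%).
A seeded simulator generates GPS-like and shuttle-video-like bouts with
known ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import critspeed as cs

# a GPS-like 1 Hz bout with known truth (S0=3.5, Ad=5.4, tc=6.4, taud=44)
truth = cs.BiExpParams.from_rest(s0=3.5, a_d=5.4, t_c=6.4, tau_g=1.5, tau_d=44.0)
trace = cs.generate_trace(cs.SimulationSpec(truth=truth, noise_sd=0.15, seed=42))

res = cs.AllOutTest(trace).fit()
print(res.summary())
```

```
    All-out test bi-exponential fit
=======================================
    parameter     estimate std err unit
---------------------------------------
   S0 (asymptote)    3.493   0.025  m/s
  Ad (decay amp.)    5.340   0.063  m/s
 Ag (growth amp.)    8.887   0.144  m/s
tc (time of peak)    7.354   0.555    s
            tau_g    1.462   0.060    s
            tau_d   43.560   0.845    s
---------------------------------------
r = 0.9963   rmse = 0.1291 m/s   converged = True
Smax = 8.833 m/s   FI = 60.46 %   S' = 256.2 m   distance = 883.7 m   anaerobic fraction = 29.0 %
classic CS = 3.638 m/s   classic D' = 226.3 m
```

The fit recovers the simulated truth to within the noise: the runner's
sustainable speed is ~3.5 m/s, the 60% fatigue index marks a large speed
reserve, and the model-based S′ (256 m) agrees with the classic window
D′ (226 m) as two estimates of the same finite capacity. `res.plot()`
draws the observed and fitted curves; `res.classic`, `res.derived` and
`res.params` expose every number programmatically.

The same analyses run from the shell:

```sh
critspeed simulate --noise-sd 0.15 --seed 42 --out bout.csv
critspeed fit bout.csv --kind speed --out report.json
critspeed predict --cs 3.77 --dprime 225.1 --distance 1000
```

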