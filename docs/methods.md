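# Methods

## The bi-exponential speed–time model

A 3-min all-out test (AOT) asks an athlete to run maximally for 180 s.
Speed rises from rest to a peak within ~3–7 s and then decays toward a
positive asymptote as the finite anaerobic capacity is spent. The model
is piecewise exponential,

    S(t) = S0 + Ad + Ag·(e^(−tc/τg) − e^(−t/τg))   t ≤ tc
    S(t) = S0 + Ad·e^(−(t−tc)/τd)                  t > tc

with all times in seconds from movement onset and speeds in m·s⁻¹. The
growth branch is written so that both branches equal `S0 + Ad` at
`t = tc`: continuity holds by construction (not as a fitted constraint)
and the curve's maximum `Smax = S0 + Ad` is attained exactly at `tc`.
This is the unique parameterisation under which `Smax` is the sum of the
asymptote and the decay amplitude and `tc` is the time to peak speed,
which is how the parameters are interpreted physiologically.

Assumptions: a single monotone effort (no pacing — a negative classic D′
is flagged, not corrected), additive measurement noise, and a decay that
is genuinely exponential toward a constant `S0` over the bout. `S0` is
the model's surrogate for critical speed; `τd` is the time over which
~63% of the `Smax − S0` gap is lost; the fatigue index
`FI% = 100·Ad/Smax` is the relative speed reserve.

### Closed-form derived quantities

All derived metrics are exact antiderivative arithmetic, no quadrature:

- `S′ = ∫ max(S(t) − S0, 0) dt` over the bout. Because the bout starts
  from rest, the growth branch begins *below* `S0`; integration starts at
  the crossing time `t* = −τg·ln(Ad/Ag + e^(−tc/τg))` (when the argument
  of the log is ≥ 1 the curve never dips below `S0` and integration
  starts at 0). The region below `S0` before `t*` is excluded from `S′`
  but its (smaller) speeds do count toward total distance.
- total distance `∫ S dt`, and the anaerobic fraction `100·S′/distance`,
  interpreted as the share of distance run above the sustainable speed.
- hyperbola predictions `speed = D′/t + CS` and `t_lim = (D − D′)/CS`,
  undefined for distances below D′.

Default bout duration is 180 s (the standard AOT) and is a parameter
everywhere.

## Preprocessing

The pipeline mirrors field practice: **differentiate** displacement
(central differences; speed is the absolute derivative so shuttle turns
are minima, not sign changes) → **zero-lag low-pass Butterworth filter**
→ **resample to 1 Hz** (linear interpolation onto the integer grid) →
**align t = 0 to bout onset**.

- "4th-order zero-lag Butterworth" is implemented as a forward–backward
  pass of a 2nd-order filter (effective order 4, zero phase), the
  standard biomechanics convention; `order=8` gives a forward–backward
  4th-order pass for sensitivity checks. Default cutoff is 4 Hz, the
  midpoint of the conventional 2–6 Hz range for running kinematics; it
  is a per-call option because no principled per-trial rule exists.
  1 Hz GPS data skip the filter (their 0.5 Hz Nyquist is below any such
  cutoff).
- Resampling requires coverage of `[0, duration]` to within one native
  sample interval; internal gaps > 2 s abort with the gap location,
  shorter dropouts (> 1.5 s) are interpolated and flagged in metadata.
- Onset alignment: t = 0 is moved to the last sample below 0.5 m·s⁻¹
  preceding the first excursion above it sustained for ≥ 2 s. Threshold
  and sustain are parameters; there is no universal convention.

## Fitting

Bounded nonlinear least squares (trust-region reflective) over all
samples, unweighted. `tc` is continuous; each residual picks its branch
by comparing the sample time with `tc`, accepting a nondifferentiable
seam at the branch boundary — the trust-region method handles this in
practice and the noiseless fixed point is exact. Bounds (a numerical
safety box, not a physiological claim): `S0 ∈ [0.5, 8]`,
`Ad ∈ [0.5, 10]`, `Ag ∈ [0.1, 50]` m·s⁻¹, `tc ∈ [1, 20]`,
`τg ∈ [0.2, 10]`, `τd ∈ [5, 200]` s.

The data-driven starting point uses the last-30-s mean for `S0`, the
peak for `Smax` and `tc`, a log-linear regression of `v − S0` on the
decay segment for `τd` (restricted to samples at least 10% of the decay
amplitude above `S0`, where the log stays nearly linear despite the upward bias
of the last-30-s `S0` estimate), `τg = tc/3`, and `Ag` from the
start-from-rest constraint `S(0) = 0`. When the single start reports
failure, a fixed 3×3 grid over `(tc, τd)` restarts the solver and the
lowest-cost converged solution is kept; everything is deterministic.
Standard errors are the usual asymptotic `σ²(JᵀJ)⁻¹` diagonal.

**Identifiability at 1 Hz.** The growth phase spans only `tc` seconds.
On a 1 Hz grid with `tc < ~2 s` there are at most two growth-phase
samples and the triple `(Ag, τg, tc)` is *exactly* non-identifiable: a
family of parameter sets reproduces every sample to machine precision.
`S0`, `Ad` and `τd` remain well determined regardless. Shuttle bouts
(peak at ~3 s) should therefore be fitted from high-rate video-derived
series when the growth parameters matter; the recovery test suite uses
10 Hz traces for this reason, and the 1 Hz round-trip checks use
linear-bout dynamics (`tc ≈ 6 s`) where the 1 Hz grid identifies all six
parameters.

## Classic window metrics

CS is the mean of the 30 one-second samples in `[150, 180)`; D′ is
`(mean of [0, 150) − CS)·150`. Half-open windows give exactly 150 and 30
samples; the inclusivity convention at the boundaries is a package
choice. On noiseless model curves the classic CS sits slightly above
`S0` (the final window has not fully reached the asymptote), and the gap
closes as `τd` shrinks.

## Cohort statistics

- The S′ regression `S′ = β1·FI + β2·τd + β3` is ordinary least squares
  (statsmodels); `SEE = √(SSE/(n−3))`, also reported as a percentage of
  mean S′. Coefficient p-values use t statistics with n−3 df. At least
  4 observations and a full-rank design are required.
- Agreement between two measures of the same quantity: the ICC is the
  two-way mixed, consistency, average-measures form (the
  Cronbach's-alpha equivalent for two items), computed from the ANOVA
  mean squares of the n×2 table as `(MS_rows − MS_err)/MS_rows`; the
  form is recorded in the output so alternative ICCs can be compared.
  Typical error is `SD(x − y)/√2` and `CV% = 100·TE/grand mean`.
- sΔ50% is the midpoint of the GET and V̇O2max speeds from a graded
  exercise test.

## The synthetic-data generator

The generator emulates the two recording modes the analysis targets: a
1 Hz GPS linear bout and an up-to-100 Hz video-derived shuttle bout. The
base curve is the model itself with additive white Gaussian noise
(default σ = 0.15 m·s⁻¹ at 1 Hz, a realistic wrist-GPS speed error),
clipped at zero, bit-reproducible given a seed.

Shuttle mode multiplies the base curve by an envelope that dips to
`1 − dip` at each 180° turn, as smooth cosine notches of fixed 1.5 s
width; turn times are placed where the *base* curve's cumulative
distance reaches successive multiples of the shuttle length (the dips
therefore shorten realised segments by a few percent — a documented
simplification). The notch shape is the simplest turn kinematics
consistent with zero-lag filtering; the generator does not model stride
mechanics, surface, wind, GPS positional drift or V̇O2 kinetics, so
passing tests demonstrate estimator correctness under the stated noise
model, not robustness to every field artefact.

Cohorts draw per-subject truths from truncated normal distributions
(confined to the fitting bounds) whose means ± SDs default to the
published group values per condition — e.g. linear: S0 3.52 ± 0.66,
Ad 5.37 ± 0.89 m·s⁻¹, tc 6.42 ± 1.96 s, τd 43.96 ± 12.73 s. Group tables
do not report the growth parameters, so `τg = 1.5 ± 0.3 s` (a plausible
sprint-acceleration constant) and `Ag` follows from the start-from-rest
constraint.

## Problem sizes and numerical checks

The test-suite simulation studies use 200 noiseless cohort draws at
10 Hz for parameter recovery (< 0.1% worst-case relative error
demanded), 30–100 noisy 1 Hz replicates for bias/precision, three
100 Hz displacement→report pipeline replicates at σ = 0.1 m·s⁻¹ (< 5%
per-parameter error demanded), and 14-subject synthetic cohorts for the
regression and agreement statistics — sizes chosen to make the checks
sharp while keeping the whole suite fast. Closed-form integrals are
verified against 0.01 s trapezoidal quadrature to 0.5%. Solver
tolerances are set near machine precision (`ftol = xtol = gtol =
1e-15`) so noiseless fixed points reproduce to ~1e-15 relative error.

## Known limitations

- Growth-phase parameters are meaningless from 1 Hz data when the peak
  occurs before ~2 s (see identifiability above).
- The classic CS and the model `S0` are distinct estimators; on finite
  bouts CS > S0 systematically and the package does not reconcile them.
- Pacing (non-all-out effort) violates the model; it is surfaced via the
  negative-D′ flag and a poor fit r, not modelled.
- The S′ regression is descriptive; no cross-validation or shrinkage is
  applied at cohort sizes of ~14.
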