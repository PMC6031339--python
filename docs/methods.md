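# Methods

## Model

Developmental progress is modelled as thermal time: within the thermal
tolerance range, developmental rate (the reciprocal of time-to-landmark)
is linear in temperature, r = aT + b. The x-intercept T0 = −b/a is the
developmental zero — the extrapolated temperature at which developmental
velocity vanishes — and K = 1/a is the thermal constant, the
degree-minutes above T0 required to reach a given landmark. Progress
under a fluctuating temperature T(t) is the integral of
max(T(t) − T0, 0), and dividing accumulated degree-minutes by
T_ref − T0 expresses it as equivalent minutes at the reference
temperature T_ref of the staging series.

Assumptions worth keeping in view:

* **Linearity.** The rate law is linear with no upper thermal cutoff;
  the model is applied at any T > T0. Real rate curves roll over near the
  upper tolerance limit, where nonlinear models (e.g. Sharpe–Schoolfield)
  would be needed; the integration API accepts only the linear clamped
  form, and adding another rate law is an extension point, not a shipped
  feature.
* **Clamping below T0.** Time below the developmental zero contributes
  exactly zero — development pauses, it does not reverse. An opt-in
  unclamped mode (`clamp_below_t0=False`) accumulates signed
  degree-minutes for strict comparisons against integer firmware
  behaviour, whose handling of sub-T0 readings is not observable from
  the outside.
* **A single T0 per population.** Defaults (T0 = 7.5 °C, T_ref = 18 °C)
  suit San Diego *Ciona*; the Japanese population's T0 is nearer 1 °C.
  T0 is a population parameter to be estimated, not a constant of the
  species.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `t0` | °C | 7.5 | developmental zero; population-specific |
| `t_ref` | °C | 18.0 | staging-series reference temperature; must exceed `t0` |
| `offset` | °C | 0.0 | additive sensor calibration (ice-bath check); warn above 2 °C |
| `integration_rule` | — | left-hold | `left-hold` or `trapezoid` |
| `clamp_below_t0` | — | true | zero contribution below `t0` |

K is not a configuration parameter: it is a property of the landmark,
estimated (K = 1/a, or D·(T − T0) directly) or supplied per experiment
(4200 °C·min for the final primary-notochord division used throughout the
examples: 400 min × 10.5 °C at the reference condition).

## Numerical choices

* **Integration.** The default rule is sample-and-hold ("left-hold"):
  each reading contributes max(T_i − t0, 0)·Δt_i, matching a device that
  polls once per interval and holds the reading. It is first-order
  accurate; a trapezoid variant of the clamped integrand (second-order
  on smooth traces) is available. Both are exact for constant traces,
  which is why two-sample constant traces reproduce the closed forms to
  machine precision.
* **Calibration order.** The sensor offset is added to raw readings
  before integration and before the mean-temperature computation: the
  device calibrates its sensor, so every displayed value uses calibrated
  temperatures.
* **Mean temperature** is time-weighted (left-hold weights, or trapezoid
  weights under that rule). At strict 1 Hz sampling this coincides with
  the per-sample arithmetic mean.
* **Degenerate inputs.** A single-sample trace spans zero time and
  returns the all-zero state with a warning rather than an error, so
  streaming use starts cleanly. Non-increasing timestamps are a hard
  error naming the first offending sample. Temperatures outside the
  sensor's physical range (−55 to 125 °C) are rejected.
* **Landmark crossing** is linearly interpolated within the bracketing
  sample interval (under left-hold the accumulator is piecewise linear
  in time, so this is exact up to the rule itself).
* **Device emulation** accumulates integer degree-milliseconds,
  truncating (floor) at each polling step — the conservative reading of
  integer arithmetic on a microcontroller. The contract tested is the
  outcome, not the rounding rule: final adjusted minutes within 1e−3
  relative of the float pipeline on runs of ten minutes or more.
  Observed worst-case disagreement on quantized 1 Hz traces is ~5e−5.
* **Stage interpolation** is linear in adjusted time between stage
  onsets, consistent with the thermal-time premise of uniform progress
  in degree-minutes; intervals are half-open [onset_i, onset_{i+1}),
  queries beyond the last onset return the last ordinal (no
  extrapolation — staging past the series is undefined biology), and
  queries before the first onset return a pre-series sentinel (`None`).

## Estimation

T0 and K are estimated by unweighted OLS of **rate on temperature** —
not duration on temperature; the two differ under noise and the linear
law holds on the rate scale. Replicates at a temperature enter as
independent observations, without pre-averaging. The reciprocal
transform makes duration noise heteroscedastic on the rate scale; this
is a documented caveat of the unweighted fit, not corrected for.

Uncertainty on the x-intercept ratio −b/a comes from a nonparametric
case-resampling percentile bootstrap (default 1000 resamples). The ratio
has heavy-tailed sampling error when the slope is small, which makes the
delta method unreliable; the bootstrap sidesteps it. Resamples with
fewer than two distinct temperatures or a non-positive slope are
discarded and redrawn (their count is reported); if more than half of
all draws are discarded the design is declared unstable and the fit is
refused. The bootstrap's inner regression is a vectorized closed-form
normal-equation solve, cross-checked in tests against both statsmodels
and a brute-force oracle.

Guard rails: fewer than two distinct temperatures is a degenerate
design; a non-positive fitted slope (development not accelerating with
temperature) refuses to report a T0 rather than returning an intercept
on the wrong side of the data.

## What the simulator emulates — and what it does not

`generate_trace` produces constant, sinusoidal, square-wave
("incubator-cycle") and step-excursion trajectories, with optional
Gaussian sensor noise and quantization to the 0.0625 °C resolution of a
12-bit digital sensor, all deterministic given a seed. These capture the
dominant features of bench and incubator records: set-point offsets,
compressor cycling, door-opening transients, sensor discretization.

`run_validation_experiment` mirrors the wet-lab design that validates
the approach: cohorts reared under different temperature profiles, each
embryo carrying a thermal budget K·(1 + ε) with ε ~ N(0, cv) —
multiplicative noise on K being the simplest mechanism consistent with
siblings dividing over a window of *adjusted* rather than real time —
scored past/not-past the landmark at fixation points given in adjusted
minutes (exactly at a fixation point counts as past). The 5% budget CV
used in tests is a modelling choice; no empirical sibling variance is
available to calibrate it.

What the synthetic data do **not** contain: circadian or seasonal
temperature structure, spatial gradients between probe and dish, probe
equilibration lag, biological stage-scoring error, or any nonlinearity
of true rate in temperature. Passing tests therefore demonstrate that
the computational chain is self-consistent and recovers its own
generating parameters under realistic noise — not that the linear model
is adequate for any particular organism or range, which only
multi-temperature wet-lab data can show.

## Study conditions and problem sizes

The in-silico validation uses three constant conditions at 18.0, 20.1
and 21.1 °C (the measured means of the original cohorts), T0 = 7.5 °C,
K = 4200 °C·min, fixations at 390/400/410 adjusted minutes, 16 embryos
per condition with 5% budget CV for the noisy variant. Noiseless, all
conditions reach the landmark at 400.0 adjusted minutes while real times
span 308.8–400.0 min (≈91 min); with noise, the between-condition spread
of mean adjusted times stays under 20% of the real-time spread (observed
≈8–10%).

Estimator-recovery simulations use 4 temperatures × 5 replicates with 2%
duration CV. The temperatures 14/17/20/23 °C span a plausible rearing
range within the organism's thermal tolerance. Recovery tests run 500
replicate datasets with a 1000-resample bootstrap each; closed-form
consistency sweeps 1000 random parameter tuples; device agreement sweeps
1000 random quantized 1 Hz traces of 10–20 minutes. These sizes keep the
full suite in the seconds-to-a-minute range while leaving the Monte
Carlo error of coverage estimates (±~1% at 500 reps) well inside the
asserted bands.

## Known limitations

* Unweighted OLS on reciprocally transformed durations (heteroscedastic);
  no errors-in-variables treatment of temperature, no clutch-level
  random effects.
* No canonical stage table ships with the package — onset times belong
  to the organism's published staging series and are supplied by the
  user as CSV.
* The linear model is extrapolated to any T > T0; no upper thermal
  limit.
* The device emulator reproduces the accumulation arithmetic, not the
  firmware binary: its truncation rule is an assumption, bounded by the
  1e−3 agreement contract.
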