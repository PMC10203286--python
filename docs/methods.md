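# Methods

This note documents the models, conventions and numerical choices behind
`runmech`, in the spirit of a package methods appendix: what each stage
assumes, which parameters matter and why their defaults were chosen, what
the synthetic generator does and does not emulate, and the known limits of
the approach.

## Signal model and conditioning

A recording is a uniformly sampled 3-channel GRF time series (vertical
`f_v`, fore-aft `f_ap` with braking negative, mediolateral `f_ml`) plus
trial metadata (body mass *m*, belt speed *s*, gravity *g* = 9.81 m/s²,
configurable). The CSV interchange dialect is comma-separated with a
mandatory header (`time_s, f_ap_N, f_ml_N, f_v_N`); the reader infers the
rate from the median time step, rejects >1% jitter, and snaps stamps to
the exact uniform grid so the container's strict-uniformity invariant
(1 ns) holds for well-behaved inputs.

Conditioning is a 5th-order Butterworth low-pass at 20 Hz applied forward
and backward (zero phase, doubled magnitude roll-off). The "fifth-order
bidirectional" wording is implemented literally: the order-5 design is run
both ways with no cutoff compensation. Filtering is linear, so per-kg
quantities are mass-invariant downstream.

## Event detection

Foot-strike/toe-off: first sample at/above and first below a 20 N vertical
threshold. Debounce: contacts shorter than 80 ms are rejected and
below-threshold gaps shorter than 20 ms merged — phases shorter than these
cannot occur at running speeds, so such excursions are noise. Contacts
touching either end of the recording are incomplete and dropped. Feet are
not labelled (single platform); strides are built from consecutive
alternating steps, since no downstream formula uses left/right identity.

Mid-stance is the first negative-to-positive fore-aft crossing followed by
at least 10 ms of non-negative force, a noise-robust reading of "the
instant the fore-aft force changes sign". Steps without such a crossing
keep their vertical variables but have braking/propulsive outputs flagged
absent.

Indices are 0-based, contacts half-open `[i_fs, i_to)`, times = index/rate.
Ten-stride analysis windows are chosen as the run of consecutive strides
whose temporal centre is nearest the requested target time (ties to the
earlier run; out-of-range targets clamp to the first/last run).

## Kinetics

* Active peak: stance maximum. Impact peak: value at the first sample —
  starting 2 samples after foot-strike to avoid edge artifacts, strictly
  before the active-peak sample — where the central-difference derivative
  of `f_v` turns negative. No prominence floor is applied.
* Vertical loading rate: ordinary least-squares slope over 20–80% of
  [foot-strike, 0.15·*t*<sub>c</sub>], using each step's own contact time;
  OLS over all window samples was preferred to a two-point difference as
  the latter is noise-fragile.
* Horizontal loading rates: peak force divided by time from phase start
  (foot-strike or mid-stance) to the peak; a peak at zero elapsed time is
  flagged rather than divided.
* Impulses: trapezoidal integrals on the uniform grid, boundary samples
  included, so braking + propulsive equals the full-stance fore-aft
  integral exactly.

## COM mechanics and work

Accelerations follow from Newton's second law; over an integer number of
strides at constant belt speed the net impulse is zero, so residual mean
acceleration is integration drift and is removed before integrating.
Integration constants implement the steady state: mean(*v*<sub>v</sub>) =
0, mean(*v*<sub>ap</sub>) = belt speed (absolute, ground-frame velocity),
mean(*v*<sub>ml</sub>) = 0. Vertical displacement is integrated once more
and linearly detrended so the window closes on itself — a single detrend
over the 10-stride window, not per-stride resets, preserving within-window
stride variability.

Δ*z* is the touchdown-to-minimum downward excursion during each stance
(standard spring-mass usage), and *k*<sub>v</sub> = *F*<sub>v,max</sub>/Δ*z*
is computed per step and averaged per window; excursions below 0.1 mm are
degenerate and flagged. Positive works sum the positive sample-to-sample
increments of *E*<sub>pot</sub> = *g z*, *E*<sub>kin</sub> = ½|**v**|² and
their sum *E*<sub>ext</sub> per unit mass, divided by distance =
belt speed × window duration (J/kg/m). By construction
*w*<sub>ext</sub> ≤ *w*<sub>pot</sub> + *w*<sub>kin</sub>.

Internal work uses the stride-frequency/duty-factor estimate
`0.08·SF·s·[1 + (DF/(1−DF))²]`. The literal expression is power-like while
the reported unit is J/kg/m; both readings are exposed
(`per_distance=False/True`), the per-distance one (division by *s*) being
the default so that the total *w*<sub>tot</sub> = *w*<sub>ext</sub> +
*w*<sub>int</sub> is dimensionally consistent. This estimate was
calibrated at slower speeds than fast treadmill running; treat it as an
approximation, not a measurement.

## Synthetic generator

Per step of duration *t*<sub>step</sub> = 1/(2·SF): vertical half-sine
with *F*<sub>max</sub> = π·*m·g*/(4·DF), which enforces per-step impulse
balance (*I*<sub>v</sub> = *m·g·t*<sub>step</sub>) and the inverse
peak–duty-factor law; fore-aft full sine of amplitude 0.15 *m·g* (a
physiological braking/propulsive peak that leaves vertical variables
untouched) with zero net impulse; `f_ml = 0`. Exhaustion drift
interpolates DF and impact probability linearly over the trial (the
transition it emulates is continuous), with SF constant.

The optional impact transient is a Gaussian bump of amplitude
`impact_amp` body weights centred at 8% of contact time with σ = 5 ms
(~20–30 ms total), i.e. a sharp early-stance collision transient. The
width matters: to create a genuine local maximum the bump's steepest
negative slope `A·e^{-1/2}/σ` must exceed the sine rise (~30 kN/s at these
conditions), which a 0.5-body-weight bump achieves at σ = 5 ms but
provably cannot at σ = 15 ms. Bernoulli draws consume one variate per step
regardless of amplitude, so the impact census is exactly monotone in
amplitude at fixed seed. All randomness derives from a single seed;
identical parameters give bit-identical output.

What the generator does **not** emulate: left/right asymmetry, step-time
variability, mediolateral force, realistic early-stance force shapes
beyond the sine + bump composite, soft-tissue resonance, or treadmill
belt-speed fluctuation. Passing the recovery suites therefore shows the
pipeline is correct for the assumed signal structure, not that it is
robust to every artifact of real force-plate data.

## Validation policy and numerical tolerances

Noiseless synthetic validation runs skip the conditioning filter
(`lowpass_hz=None`): zero-phase low-passing smooths the instantaneous
touchdown of the ideal waveform and biases threshold crossings by ~10 ms,
and it attenuates any sub-20 Hz-bandwidth transient below detectability on
the steep sine rise — both filter properties, not pipeline defects. The
filter itself is validated separately against the analytic Butterworth
magnitude response, and noisy-data tests follow the full
filter-then-detect protocol.

On noiseless 60 s trials at 1000 Hz the pipeline recovers contact/flight
times within 2 ms (the threshold-crossing offset `(t_c/π)·asin(20/F_max)`
plus one-sample quantization), SF/DF within 0.005, the active peak within
0.5%, and impulse balance within 0.5%. COM quantities are checked against
an independently coded quadrature oracle on a 200 000-point grid: Δ*z* and
*k*<sub>v</sub> agree within 2% (the residual is foot-strike sampling of
*z*), works within 2% (observed ≪ 1%). Test problem sizes (15–60 s trials,
10-stride windows) keep the full suite under ~10 s while giving every
window 20 steps of statistics.

## Known limitations

* The impact detector reports at most one impact peak per step and has no
  amplitude floor; on unfiltered noisy data it will fire spuriously —
  always condition real recordings first.
* COM integration assumes steady-state treadmill running over an integer
  stride count; overground or accelerating trials violate the constraints.
* Vertical stiffness averages per-step ratios; computing it from
  window-mean quantities instead would differ slightly for variable
  strides.
* Group statistics include the chi-squared census comparison and Holm
  adjustment; repeated-measures ANOVA with sphericity corrections is
  deliberately out of scope — the tidy per-window output is ready for any
  standard statistical tool.
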