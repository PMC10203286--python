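# runmech

Force-platform analysis of treadmill running, from raw ground-reaction-force
(GRF) time series to the variables sports biomechanists report when they
study how running form changes — for example with fatigue during exhaustive
runs near and above peak aerobic speed:

* **spatiotemporal variables** — contact time *t*<sub>c</sub>, flight time
  *t*<sub>f</sub>, swing time *t*<sub>s</sub>, braking/propulsive times,
  stride frequency SF = (*t*<sub>c</sub> + *t*<sub>s</sub>)⁻¹ and duty
  factor DF = *t*<sub>c</sub>·(*t*<sub>c</sub> + *t*<sub>s</sub>)⁻¹;
* **kinetics** — active peak *F*<sub>v,max</sub>, impact peak
  *F*<sub>v,impact</sub> (first negative derivative of the vertical GRF
  before the *F*<sub>v,max</sub> instant), braking/propulsive peaks,
  vertical/braking/propulsive loading rates and impulses;
* **centre-of-mass (COM) mechanics** — 3-D COM velocities by single
  integration and vertical displacement by double integration of the GRF,
  the downward excursion Δ*z* during contact, and vertical stiffness
  *k*<sub>v</sub> = *F*<sub>v,max</sub>/Δ*z* (spring-mass model);
* **positive mechanical work** (J/kg/m) — external work as the sum of
  positive increments of *E*<sub>pot</sub> + *E*<sub>kin</sub> of the COM,
  internal work estimated as
  *W*<sub>int</sub> = 0.08 · SF · *s* · [1 + (DF/(1−DF))²],
  and their total;
* **study-level statistics** — peak aerobic speed
  PS = *s*<sub>last-inc</sub> + αΔ*s* (Δ*s* = 0.28 m/s), impact-peak
  census, chi-squared goodness-of-fit tests, Holm adjustment and
  mean ± SD group summaries.

Because raw force recordings of this kind are rarely shared, the package
includes a first-class synthetic GRF generator with known ground truth:
impulse-balanced half-sine vertical lobes
(*F*<sub>max</sub> = π·*m·g*/(4·DF), so each step's vertical impulse equals
body weight × step time), biphasic zero-net-impulse fore-aft force,
optional early-stance impact transients, additive noise and a linear
exhaustion drift (DF and impact probability up, SF constant). Every stage
of the pipeline is validated against this generator and against
independent quadrature oracles.

## Worked example

Simulate a fatiguing 60 s run (duty factor drifting 0.26 → 0.30, impact
probability 0.1 → 0.8, stride frequency fixed at 1.4 Hz) and analyze ten
consecutive strides near the start, middle and end:

```python
from runmech import SimParams, simulate_trial, TrialModel

rec, truth = simulate_trial(SimParams(duration=60, df=0.26, df_end=0.30,
                                      impact_amp=0.6, impact_prob=0.1,
                                      impact_prob_end=0.8, seed=5))
res = TrialModel(rec, lowpass_hz=None).fit(windows={"start": 5, "mid": 30, "end": 55})
print(res.summary())
```

```
Treadmill trial analysis
  mass 70.0 kg | belt 4.77 m/s | 1000 Hz | 60.0 s | 3 window(s) of 10 strides

  window steps           t_c[s]           t_f[s]           sf[Hz]               df      f_v_max[BW]        k_v[kN/m]    w_ext[J/kg/m]    w_tot[J/kg/m]
   start    20     0.187±0.001      0.170±0.001      1.400±0.001      0.262±0.002      2.984±0.016     34.232±2.982             0.805            0.931
     mid    20     0.199±0.001      0.158±0.001      1.400±0.001      0.278±0.002      2.806±0.014     31.760±2.638             0.799            0.928
     end    20     0.210±0.001      0.147±0.001      1.400±0.001      0.295±0.002      2.649±0.013     30.037±1.906             0.795            0.926

impact-peak steps per window: start=5, mid=7, end=16
```

Reading the table: with growing "fatigue" the contact time lengthens
(0.187 → 0.210 s) and the flight time shortens while stride frequency is
untouched; the active vertical peak falls from 2.98 to 2.65 body weights
(the sine-model law *F*<sub>v,max</sub> ∝ 1/DF), vertical stiffness drops,
the external work per kilogram-metre is essentially unchanged, and the
number of steps showing an impact peak triples — a "smoother" yet
mechanically equally expensive running pattern.

Per-step tables (`res.per_step()`), window work summaries
(`res.work_table()`), a JSON results document (`res.save(path)`) and GRF
plots (`res.plot_grf("mid")`) hang off the results object. A thin CLI
mirrors the library: `runmech simulate`, `runmech analyze`,
`runmech stats chisq`.

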