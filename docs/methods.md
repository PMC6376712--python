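# Methods

## Physical model

The operated thigh is modelled as a homogeneous 1-D slab of fat–water
mixture of depth L = 10 cm, with the skin surface at x = 0 and depth
increasing inward. Tissue temperature Φ(x, t) (°C) satisfies the heat
equation ∂Φ/∂t = α ∂²Φ/∂x² with

* Φ(0, t) = T_meas(t): the measured (or synthetic) skin-temperature
  trace, a Dirichlet boundary sampled every 10 s and linearly
  interpolated onto the solver grid;
* Φ(L, t) = T₀: the subject's pre-treatment core temperature at the
  deep boundary;
* Φ(x, 0) = T₀ for interior nodes. The surface node at t = 0 takes the
  first boundary sample, which is the skin baseline (~32 °C), not the
  core temperature — measured traces start continuous, not at a jump.

The model deliberately omits blood perfusion (no Pennes term), layered
tissue, and 2-D/3-D geometry. Perfusion makes the model overestimate
cooling at depth while the flat-plate geometry underestimates it; the
two biases act in opposite directions (see Limitations).

### Thermal diffusivity

Assuming a homogeneous fat–water mixture, α is interpolated linearly
between plain water (0.149 × 10⁻⁶ m²/s, 0 % fat) and fat
(0.100 × 10⁻⁶ m²/s, 100 % fat) by the subject's body-fat fraction.
BF% comes from the adult Deurenberg regression
BF% = 1.2·BMI + 0.23·age − 10.8·[male] − 5.4, clamped to [0, 100]
(extreme synthetic anthropometrics can push the linear relation out of
range). The coefficients live in a `BodyFatCoefficients` object so an
alternative body-composition relation can be substituted. BMI is
weight/height²; heights arrive in cm in file input and are converted
to metres internally.

### Discretisation

Crank–Nicolson time stepping on the default grid dx = 0.1 mm,
dt = 1 s, duration 30 min (1001 nodes × 1800 steps). The diffusion
number α·dt/dx² is ≈ 13 at these settings, so an explicit scheme would
be unstable; CN is unconditionally stable and second order in both
steps. The interior tridiagonal system (I + r/2·A), constant over
time, is LU-factorised once and solved directly each step.

Numerical choices worth knowing:

* **Verification.** The solver is checked against the closed-form
  semi-infinite-solid solution Φ = Ts + (T₀ − Ts)·erf(x/2√(αt)) for a
  step boundary — valid here because 30 min of cooling penetrates
  √(αt) ≈ 1.5 cm, far from the 10-cm deep boundary. Agreement is
  ≲ 10⁻⁴ °C at depths ≤ 3 cm and the observed convergence order is 2
  (error ratio 4.0 when dt and dx are halved).
* **Start-up ringing.** A boundary that jumps at t = 0 (e.g. the
  verification step case) excites bounded CN oscillations near the
  surface (undershoot ~0.5 °C at default resolution). Measured and
  synthetic traces start at the skin baseline, so the default solve is
  smooth and satisfies the discrete maximum principle to within
  0.1 °C. An optional Rannacher start-up (two fully implicit half
  steps, `SolverConfig(rannacher_startup=True)`) removes the step
  ringing entirely; it is off by default to keep the scheme exactly
  the reference CN.
* **Interpolation.** Boundary samples between grid times, and field
  values between grid depths, are linearly interpolated. X-ray
  distances carry millimetre-scale measurement error, far above the
  0.1-mm grid interpolation error.

## Depth summaries and thresholds

For each subject the model input site follows the implant: mid femur
for DHS/HA/THA (where soft-tissue trauma concentrates), trochanter for
an intramedullary nail (the nail entry point). A treatment trace whose
minimum never drops below 30 °C (configurable) is flagged as an
uncovered probe and excluded with a logged warning.

`summarize_depth` reports min/mean/max of Φ at a depth over the
treatment window [0, 30 min], both endpoints included; the cohort
depth table then averages these per radiograph dimension (A trochanter,
B central, C distal, D fracture distance). The time-average per subject
is computed first and cohort-averaged second. `fraction_below` exposes
both the strict ("< 30 mm") and inclusive ("≤ 20 mm") conventions
explicitly, since clinical reports mix them.

Threshold timings are computed by linear interpolation between 10-s
samples: total treatment time below the 13.6 °C skin-analgesia
threshold, time after cessation until the rewarming trace re-exceeds
it, and time until the trace first comes within 0.5 °C (configurable)
of the pre-treatment baseline, defined as the first treatment-phase
sample. "Baseline reached" has no standard numerical definition; the
0.5 °C tolerance is this package's choice and is configurable.

## Pain statistics

Treatment effect per cycle is NRS improvement = pre − post. The
pipeline's statistics are deliberately simple and fully specified:

* Pearson correlation between per-cycle improvement and the subject's
  predicted temperature drop (baseline skin temperature minus mean
  simulated temperature at the central (B) distance, configurable),
  with a Fisher-z 95 % CI and two-sided p;
* OLS slope of post-treatment NRS on time since surgery, reported per
  6 h (the cycle spacing), with t-based CI.

Records missing either score are dropped pairwise with a logged count.
Covariate-adjusted mixed-model analyses are out of scope by design;
the per-record table is exposed so such models can be fitted with
external tools.

## Synthetic cohort generator

The generator emulates the published cohort structure so the pipeline
is fully testable without patient data. Defaults (all configurable in
`GeneratorParams`):

| Quantity | Default | Note |
|---|---|---|
| n subjects | 35 | 26/35 female |
| age | 80.5 ± 8 yr, truncated [40, 95] | |
| BMI | median 22 in [20, 34] | log-normal; location calibrated so the *truncated* median is 22 |
| surgery mix | 9 DHS / 6 HA / 6 THA / 14 IMHN | |
| core temperature | 37.2 ± 0.6 °C | |
| skin baseline | 32.1 ± 2.0 °C | |
| treatment end temp | 18.2 ± 4.0 °C, floor 10 °C | site offsets: trochanter +1.5, distal −1.0; contralateral barely cools |
| cooling time constant τ_c | 5 min | fastest decline in the first 5 min |
| rewarming time constant τ_r | 50 min | satisfies both published rewarming anchors simultaneously |
| sensor noise | 0.2 °C SD at 10-s sampling | |
| X-ray distances (mm) | A 34.1±13.8, B 42.6±13.6, C 37.6±11.6, D 59.6±10.8, floor 5 | |
| NRS post trajectory | start 3.0, decline 0.14 per 6 h, noise SD 1.9 | 12 cycles at 6-h spacing |
| improvement | mean 1.5, SD 1.0, plus β·(temp drop) | β = 0 by default |

Traces are single exponentials per phase — the simplest shape
consistent with every published summary anchor: treatment
T(t) = T_end + (T_base − T_end)·e^(−t/τ_c); rewarming
T(t) = T_base − (T_base − T_min)·e^(−t/τ_r), continuous at the phase
junction and never exceeding baseline (no reactive hyperthermia). With
baseline 32.1 °C, minimum 11.5 °C and τ_r = 50 min, the analytic
inversions give re-crossing of 13.6 °C at 5.38 min and baseline − 0.5 °C
at 185.9 min, matching the observed 5.5 min and ~179 min.

Pain scores are integers clamped to 0–10. Clamping a latent normal at
the floor would silently raise low means and flatten a configured
linear trend by ~15 %; the generator therefore inverts the
clamped-integer mean function (monotone; Brent root find) so the
*emitted* scores follow the configured mean trajectory exactly. The
configured decline is thus a property of the observable data, and OLS
recovery is unbiased by construction. The same calibration applies to
the injected-association improvement means.

Every draw flows from one seed through named substreams per subject,
data kind and probe site (CRC-keyed `SeedSequence`), so adding
subjects or sites never reshuffles earlier draws, and identical
parameters plus seed give bit-identical outputs.

What the generator does **not** emulate: pressure-setting effects on
cooling efficacy (the underlying observations conflict), intra-subject
day-to-day correlation of traces, wrap-application heterogeneity, and
any real covariance between anthropometrics and cooling efficacy.
Passing tests on synthetic cohorts therefore demonstrate correctness
of the pipeline's computations under the stated conditions, not
clinical validity on real patients.

## Problem sizes

The default test and acceptance runs use: one full-resolution solve
per verification case (1001 × 1801 grid), 200 noisy traces for the
rewarming timings, and 200 replicate cohorts of 25 subjects × 12
cycles for trend recovery. Pipeline tests run on a 0.5–1 mm / 5–10 s
grid, which differs from the reference grid by a few hundredths of a
degree at clinically relevant depths.

## Known limitations

* **No perfusion, flat-plate geometry.** The conduction-only slab
  overestimates cooling at depth (no warm blood supply) while the
  planar geometry underestimates it; the net bias is unquantified.
* **Deep predictions run warm under a core-temperature start.** With
  the body initialised at T₀ = 37 °C and a surface trace that never
  drops below ~18 °C, conduction alone cannot cool tissue at 3 cm
  below ~34 °C in 30 min — the erf bound for an instantaneous step to
  18.2 °C is 33.9 °C. Published deep-tissue values around 30 °C at
  3 cm imply an effectively cooler initial/deep condition (~33 °C)
  than the stated core temperature. This package follows the stated
  boundary conditions; its 3-cm prediction is accordingly warmer than
  the published figure, and the discrepancy is reported rather than
  calibrated away.
* **Noisy first-crossing detection biases baseline-return times
  early.** Near baseline the rewarming slope is ~0.01 °C/min, so
  0.2 °C sensor noise triggers the ±0.5 °C criterion up to tens of
  minutes before the noiseless trace would cross; the 200-trace mean
  sits ~25 min below the noiseless value. Any first-passage detector
  on noisy data shares this property; smoothing before detection would
  trade it for lag.
* **Body composition from BMI only.** Skinfold-based estimates are out
  of scope; the Deurenberg relation carries its own population-level
  error, which propagates into α within the water–fat bounds.
* **Statistics are unadjusted.** The Pearson/OLS analyses do not
  adjust for sex, BMI, surgery type, fracture type or pressure
  settings; export the per-record table for mixed-model analyses.
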