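# cryodepth

**How deep does cryotherapy cool?** `cryodepth` predicts deep-tissue
temperature in postoperative hip-fracture patients during
continuous-flow cryocompression therapy (CFCT): a chilled-water wrap
with intermittent pneumatic compression applied to the operated thigh
for 30-minute cycles. Cooling the skin below 13.6 °C produces skin
analgesia, but hypothermia also impairs fibroblast and osteoblast
function — so whether the cooling front reaches muscle and bone, and
whether deep cooling relates to pain relief, are clinically meaningful
questions that cannot be answered by skin probes alone.

The package is aimed at clinical physicists and researchers analysing
cryotherapy protocols. It provides:

* **Heat model.** The thigh is treated as a homogeneous 1-D slab of
  fat–water mixture. Tissue temperature Φ(x, t) obeys the heat equation

      ∂Φ/∂t = α ∂²Φ/∂x²,  0 ≤ x ≤ L = 10 cm,

  with Dirichlet conditions Φ(0, t) = T_meas(t) (the measured skin
  trace), Φ(L, t) = T₀ (core temperature), and Φ(x, 0) = T₀. The
  solver uses the Crank–Nicolson scheme (second order, unconditionally
  stable) on a 0.1 mm × 1 s grid, with a direct tridiagonal solve each
  step, and is verified against the semi-infinite-solid erf solution.
* **Tissue properties.** α is interpolated linearly between water
  (0.149 × 10⁻⁶ m²/s) and fat (0.100 × 10⁻⁶ m²/s) by body-fat
  percentage, estimated from BMI, age and sex via the Deurenberg
  relation (coefficients configurable).
* **Depth summaries.** Min/mean/max temperature over the treatment
  window at X-ray-derived skin-to-bone distances (calibrated against
  implants of known dimensions), thin-soft-tissue cohort fractions, and
  rewarming threshold timings (analgesia re-crossing, baseline return).
* **Pain statistics.** Per-cycle NRS improvement (pre − post), its
  Pearson association with the predicted temperature drop (Fisher-z CI),
  and the OLS trend of post-treatment NRS over the first 72 h.
* **Synthetic cohort generator.** Reproducible, seeded subjects, skin
  traces, X-ray distances and pain trajectories emulating the published
  cohort structure, so the full pipeline runs without any patient data.

## Worked example

`examples/01_depth_of_cooling.py` solves the cohort-average case: skin
falling exponentially (5-min time constant) from 32.1 °C through
18.2 °C at 30 min, diffusivity from the cohort-median subject (BMI 22,
age 80, female), core temperature 37 °C:

```text
cohort-median subject: BF% = 39.4, alpha = 1.297e-07 m^2/s

end-of-treatment temperature by depth:
  1 cm:  25.4 degC
  2 cm:  31.0 degC
  3 cm:  34.4 degC
  4 cm:  36.1 degC
  5 cm:  36.7 degC
```

A 30-minute treatment cools tissue appreciably to about 2–3 cm; beyond
that the body remains near core temperature. Since a substantial
fraction of hip-fracture patients have less than 30 mm of lateral soft
tissue at the trochanter, the front can reach bone in lean patients.
The other examples verify the solver against the analytic oracle,
generate and summarise a synthetic cohort, time the rewarming
thresholds (skin analgesia persists ~5 min after wrap removal; baseline
returns after ~3 h) and run the full pipeline.

There is also a thin CLI:

```bash
cryodepth generate --outdir data --seed 1     # synthetic input CSVs
cryodepth all --config config.yaml            # full pipeline
```

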