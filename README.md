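# renal-mpmri

Multiparametric ¹H-MRI analysis of renal lesions in a transgenic mouse model
of tuberous sclerosis complex (TSC), built as a fully simulatable pipeline.
TSC kidneys carry dozens of small bilateral cystadenomas (cystic, papillary
and solid phenotypes) whose growth and response to mTOR inhibition are
monitored with T2-weighted volumetry, diffusion-weighted ADC mapping,
variable-flip-angle T1 mapping and dynamic contrast-enhanced (DCE) MRI. This
package implements every stage of that analysis together with a digital
phantom generator, so each estimator can be validated by round-trip parameter
recovery against exact ground truth.

## What it computes

- **Digital phantom** (`renal_mpmri.phantom`): bilateral ellipsoidal kidneys
  bearing ~36 (sd 5.7) ellipsoidal lesions per animal spanning
  0.016–5.12 mm³, three tissue classes with distinct T1/T2/ADC/K^trans, and
  forward simulation of the four protocol acquisitions (T2w FSE; DWI at
  b = 25/180/323/508 s/mm²; SPGR at flip angles 2–40°, TR = 39 ms; DCE at
  5 s × 50 frames) with Rician magnitude noise.
- **ADC mapping** (`renal_mpmri.diffusion`): mono-exponential
  S = S₀·exp(−b·ADC), log-linear (default) or nonlinear least squares.
- **T1 mapping** (`renal_mpmri.relaxometry`): DESPOT1 — regress S/sin α on
  S/tan α so the slope is E1 = exp(−TR/T1) — plus a nonlinear SPGR
  cross-check, and blood-normalized T2-weighted intensity.
- **DCE analysis** (`renal_mpmri.dce`): bolus-arrival detection, SPGR signal
  inversion to gadolinium concentration C(t) = (R1(t) − R1₀)/r1, the six
  semi-quantitative parameters (AUC, iAUC₉₀, wash-in/wash-out slopes,
  time-to-peak, peak), and the standard Tofts fit
  Ct(t) = K^trans ∫ Cp(τ) e^(−kep(t−τ)) dτ against a biexponential
  population AIF (closed form).
- **Volumetry** (`renal_mpmri.volumetry`): stacked-2D-ROI lesion volumes, a
  deterministic rater emulator for digitizing ground-truth lesions,
  Bland–Altman agreement (bias ± 1.96·SD), SNR/CNR and parameter
  correlations.
- **Response** (`renal_mpmri.longitudinal`): percent change from baseline
  (lesion or total-burden level), per-lesion slopes per day with group
  summaries, and ADC-threshold classification (cystic > 0.0022 mm²/s,
  papillary ≤ 0.0012 mm²/s).

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated data
and write tidy tables under `results/` (images under `scratch/`):

```
python analysis/01_simulate_study.py
python analysis/02_optimal_detection.py
python analysis/03_baseline_characterization.py
python analysis/04_response.py
```

`02_optimal_detection.py` prints, for the seed-7 phantom animal:

```
axial vs coronal (1 mm): r = 0.98 (p = 5.3e-17), bias = 0.090 mm3, LoA [-0.326, 0.505], n = 23
1 mm vs 0.5 mm (axial): r = 0.98 (p = 3.7e-19), bias = 0.082 mm3, LoA [-0.356, 0.520], n = 27
overestimation ratio 1mm/0.5mm: 2.64 for lesions <= 0.25 mm3 (n=9) vs 1.08 for > 1 mm3 (n=7)
```

i.e. volumes read from different orientations agree tightly, 1 mm slices
overestimate sub-0.25 mm³ lesions by more than two-fold while large lesions
are unaffected (the partial-volume effect that motivates 0.5 mm slices), and
`03_baseline_characterization.py` reproduces the characteristic baseline
physiology — e.g. larger lesions are less permeable
(`corr(volume, K^trans): r = -0.55`) because the big lesions are
predominantly cystic. `04_response.py` shows the treated cohort's tumor
burden plateauing near +35 % of baseline while controls keep growing, with
normalized-T2 slopes of opposite sign (+0.091/day treated vs −0.095/day
control).

A `renal-mpmri` CLI (subcommands `simulate`, `fit-adc`, `fit-t1`, `dce`,
`volumes`, `agree`, `respond`, `run`) wraps the same stages for use on
NIfTI + YAML-sidecar inputs.

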