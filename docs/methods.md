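# Methods

This note records the models implemented in `renal_mpmri`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would need to know.

## Signal models

**Diffusion.** The DWI signal is mono-exponential, S(b) = S₀ exp(−b·ADC),
over the protocol's four b-values (25, 180, 323, 508 s/mm²). No b = 0 image
is acquired, so S₀ is always an extrapolated fit parameter. The default
estimator is the closed-form log-linear least-squares fit; a signal-domain
nonlinear fit is provided because at low SNR the log transform reweights the
Rician noise unfavourably. Estimated ADC is clipped to the physical window
[0, 0.01] mm²/s with out-of-range voxels flagged. Voxels with non-positive
signal are excluded and counted in the QC table — never silently zeroed and
never an exception.

**T1 (VFA/DESPOT1).** The spoiled-gradient-echo steady state is
S(α) = M0 sin α (1 − E1)/(1 − E1 cos α), E1 = exp(−TR/T1), at the seven
protocol angles (2–40°) and TR = 39 ms. The linearization S/sin α =
E1·(S/tan α) + M0(1 − E1) is fitted per voxel by OLS; slope outside (0, 1)
or fewer than three positive-signal angles marks the voxel unfittable. The
nonlinear SPGR fit (`fit_t1_nls`) is kept as an independent route; on
noiseless inputs the two agree to well under 0.5 %. TE decay is constant per
series and folds into M0.

**T2-weighted intensity.** Simulated as S = pd·exp(−TE/T2), optionally
multiplied by the saturation factor (1 − exp(−TR/T1)) when comparing
repetition-time regimes (2D TR = 3 s vs 3D TR = 0.2 s). Lesion T2w intensity
is reported as the ratio to a blood-vessel reference ROI, which is treated as
an operator-placed input: the ratio is gain-invariant and anchors
longitudinal comparisons because blood is not expected to change with age or
therapy. A non-positive vessel mean is an error, not a statistic.

**DCE.** The arterial input is a population biexponential,
Cp(t) = D(a₁e^(−m₁t) + a₂e^(−m₂t)) with D = 0.27 mmol/kg and defaults
a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹ — the classic
Gd-DTPA parametrization, configurable because the study's own AIF is not
measurable from the data at hand. Tissue concentration follows the standard
Tofts model; with a biexponential AIF the convolution has the exact form
Ct(t) = K^trans D Σ aᵢ(e^(−kep t) − e^(−mᵢ t))/(mᵢ − kep), with the
aᵢ·t·e^(−mᵢt) limit taken when |mᵢ − kep| < 10⁻⁹. A trapezoidal numerical
convolution implements the same integral independently and the two routes are
required to agree to 10⁻⁶ relative at the study's kinetic rates (the
trapezoid error grows as (Δτ·kep)², so stiffer rates need a finer grid than
0.1 s).

Signal→concentration inverts the SPGR equation against the pre-contrast T1:
the baseline-relative ratio cancels M0·sinα, giving E1(t) and hence
R1(t) = −ln E1/TR and C(t) = (R1 − R1₀)/r1 with r1 = 3.4 s⁻¹mM⁻¹ (high-field
Gd-DTPA, configurable). Ratios outside the invertible range are clipped to
zero enhancement and the curve is marked low-confidence. Pre-arrival frames
are forced to zero. No hematocrit correction is applied by default (the AIF
is treated as a plasma curve); a correction factor can be folded into the
AIF amplitudes.

Bolus arrival is detected on ROI-mean curves (the per-lesion analysis unit)
as the first frame exceeding baseline mean + 3·SD for 2 consecutive frames;
a flat curve yields an explicit no-arrival result and the lesion is excluded.
Because concentration is still zero at the arrival instant itself, detection
lands on the first enhanced frame — within one frame of truth, which is the
tolerance used in the Monte-Carlo checks.

The six semi-quantitative descriptors follow the literal sum convention: AUC
and iAUC₉₀ are sums of per-frame concentrations (units mM) over all frames
and over [t_arrival, t_arrival + 90 s] respectively; a Δt-scaled trapezoidal
variant (mM·s) is available behind `time_integrated=True`. Wash-in is the
chord slope arrival→peak; wash-out is the OLS slope peak→last frame with
positive slopes allowed. Time-to-peak is measured from arrival (a
from-series-start variant is flaggable). The peak is searched from arrival
onward and ties break to the earliest frame; a peak at the arrival (no
wash-in) or last frame (no wash-out) produces an explicit `None`.

The Tofts fit is bounded least squares (K^trans ∈ [0, 5] min⁻¹,
ve ∈ (0.01, 1]) with five log-spaced K^trans starts and the best-RMSE
convergent solution retained; the convergence flag reflects the optimizer
verdict. An identically-zero curve returns K^trans = 0 with ve flagged
unidentifiable.

## The phantom

Two ellipsoidal kidneys (semi-axes 3.5 × 4.5 × 6 mm) in a 30 × 30 mm field
of view with a midline vessel for T2 normalization. Lesion count is drawn
from Normal(36, 5.7) truncated at ≥ 1; positions are biased to the kidney
periphery (60–95 % of the shell radius), matching the capsule/pelvis
predilection of TSC cystadenomas. Classes follow the histological mix of
untreated kidneys (60 % cystic, 19 % papillary, 21 % solid); volumes are
log-uniform within 0.016–5.12 mm³, with cystic lesions drawn from the upper
part of the range and papillary/solid from the lower part — this is what
produces the negative volume–K^trans and volume–peak correlations as an
emergent property rather than an imposed one. Tissue parameters sit at the
study's operating points (lesion ADC clipped to 0.0007–0.0033 mm²/s around
0.0019; T1 near 3 s; K^trans 0.04 min⁻¹ cystic vs 0.33 min⁻¹ solid) with
15 % log-normal per-lesion jitter.

Rasterization computes each voxel's tissue volume fractions by subsample
counting: per axis the voxel is subdivided at least 4× (refined up to 32× so
that ≥ 8 subsamples span each lesion semi-axis — without refinement the
smallest lesions against 0.5 mm slices misrender by several percent; with
it, voxel-fraction volume agrees with the analytic ellipsoid volume to
≤ 0.5 % across the full size range). Overlapping lesions are resolved
deterministically by ascending lesion id: each structure claims
min(fraction, remaining), so a later lesion can only occupy what earlier
structures left. Maps are the claim-weighted parameter mixture, with
parenchyma and background taking the remainder.

Noise is Rician on the magnitude (two Gaussian channels of scale σ), the
standard model for magnitude MR; σ is quoted as reference-signal/SNR.

**What the phantom does not emulate:** k-space sampling and reconstruction,
motion/respiratory artifacts, B1 inhomogeneity, fat signal, intra-lesion
heterogeneity (each lesion is internally uniform) and rater variability
(digitization is deterministic). Passing round-trip tests therefore
demonstrates estimator correctness under the stated signal models, not
robustness to those real-world effects.

## Rater-emulating volumetry

Manual volumetry in this setting outlines each lesion on every 2D slice where
it is visible, and the volume is (in-plane area) × (slice thickness).
`digitize_lesion` emulates this with a slice-centre cross-section rule: for
each slice whose centre plane cuts the lesion, the analytic in-plane
cross-section at that plane is supersampled and voxels with area fraction
≥ 0.5 enter the mask. Two consequences mirror the empirical behaviour of
thick-slice volumetry: (i) every intersected slice contributes its full
thickness, so lesions small against the slice thickness are overestimated
(≈ 2.6× ratio between 1 mm and 0.5 mm readings below 0.25 mm³, converging to
≈ 1 above 1 mm³), and (ii) a small lesion sitting between slice centres can
be missed entirely, reproducing the thickness-dependent detection floor. A
volume-fraction thresholding rule was considered and rejected: it is nearly
volume-preserving (no thickness-driven overestimation) and deletes small
lesions instead of inflating them, which contradicts how human raters behave.
The 0.5 in-plane threshold is the lever controlling residual bias and is
exposed as a parameter.

Bland–Altman uses the sample (n−1) standard deviation and the fixed 1.96
multiplier; Pearson r/p are reported as explicit no-values when either
reading has zero variance. Lesions from different stacks are matched by
maximum 3D world-space overlap on a common fine grid with greedy assignment.

## Longitudinal cohort generator

The response stage works on summary records, not images. Volume change from
baseline follows the study's weekly group means (control 28/62/71 %, treated
36/39/39 %) with the printed dispersions treated as *lesion-level* SD plus a
10 % multiplicative animal-level effect — the within-animal lesion
heterogeneity dominates, as individual lesions both grow and shrink under
therapy. ADC, T1 and normalized-T2 evolve linearly per day at the group
slopes (T1: +0.0276 control / −0.0058 treated; T2norm: −0.1058 / +0.0841;
ADC slopes derived from the endpoint means: +1.9×10⁻⁵ treated, −2×10⁻⁶
control) with lesion- and animal-level slope heterogeneity and additive
measurement noise. Missing weeks are handled by omission, never imputation.
Group inferential statistics (repeated-measures ANOVA, mixed models) are
exported as tidy long-format tables for external statistical software rather
than reimplemented.

ADC classification: cystic above 0.0022 mm²/s; papillary at or below
0.0012 mm²/s (taken from the cited renal-RCC ADC literature, exposed in
config since the boundary is not uniquely fixed); boundaries go to the lower
class, making the rule monotone in ADC.

## Numerical and design notes

- All randomness flows from one seed through named substreams
  (`numpy.random.SeedSequence`); fixed-seed runs are byte-reproducible,
  including CSV outputs of the full pipeline.
- The DCE protocol's in-plane resolution is taken as FOV/matrix
  (30/128 ≈ 0.234 mm); a nominal 0.3125 mm figure circulating for this
  protocol is inconsistent with its own FOV and matrix and is not used.
- ROI statistics use the sample (n−1) SD, with SD = 0 reported for
  single-voxel ROIs; an ROI with no fitted voxels returns an explicit
  no-value object rather than NaNs.
- `simulate_dce` evaluates the closed-form concentration once per unique
  (K^trans, ve) pair, which makes piecewise-constant phantoms cheap while
  remaining exact.
- Acceptance-scale problem sizes (10⁴-voxel noise studies, 500 DCE
  replicates, 40–100 cohort replicates, 8 sub-voxel offsets for volumetry
  convergence) keep Monte-Carlo error an order of magnitude below every
  tolerance they are checked against.

## Known limitations

- The standard Tofts model has no vascular term (vp) and the AIF is assumed,
  not measured; fitted K^trans is therefore model-conditional.
- DESPOT1 is unweighted; at very low SNR its noise propagation is worse than
  the nonlinear fit's, which is why both are provided.
- The rater emulator is deterministic and cannot reproduce inter-observer
  variability; agreement statistics on phantom data bound only the
  geometry-driven component of disagreement.
- Tissue parameters are class-constant up to scalar jitter; spatial gradients
  within lesions (e.g. the non-enhancing cyst core of large lesions) are only
  represented insofar as partial-volume mixing creates them at boundaries.
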