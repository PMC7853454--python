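# Methods

## Scope and data model

`dynpet` analyzes one-bed-position dynamic PET acquisitions stored as 4-D
NIfTI volumes of decay-corrected activity concentration (Bq/mL) with a JSON
sidecar carrying frame timing (seconds post-injection, BIDS-PET field
names) and the subject data needed for SUL normalization. Regions are given
as a 3-D integer label map on the same voxel grid; no resampling is
performed — a grid mismatch is an error, because silent resampling would
confound the quantification being studied. The representative time of a
frame is its mid-point, reported in minutes; this convention is used by
every module.

## SUL and TBR

SUL = C · LBM[g] / A₀[Bq], linear in the region-mean concentration C. LBM
defaults to the Janmahasatian fat-free-mass model (males
9270·W/(6680 + 216·BMI), females 9270·W/(8780 + 244·BMI)), the common
convention when "SUL" is reported; the James formula is selectable. The
formula's output is validated against 0 < LBM ≤ weight and rejected
otherwise (the fat-free-mass model exceeds body weight below BMI ≈ 12,
outside its validity range). TBR is the pointwise ratio of lesion SUL to
the image-derived arterial input SUL, masked where blood SUL ≤ 0; the
scalar TBR defaults to the final analyzed frame and is configurable,
because the time point of a reported single-number TBR varies between
protocols.

ROIs below 1.8 mL (a 15-mm-diameter sphere) are *flagged* undersized and
logged, not rejected: partial-volume bias is a caveat the analyst must see,
but a hard failure would make small-lesion studies impossible. The arterial
ROI is deliberately a narrow cylinder in practice and is exempt, with its
own 0.3 mL floor.

## Curve-shape detectors

**Plateau.** The slope is estimated by least squares over a sliding window
of 3 consecutive frames (robust to single-frame noise, unlike a 2-point
difference). The plateau time is the mean mid-time of the earliest window —
after the curve's global peak, ties to the earliest frame — whose slope and
*every later window's* slope satisfy |slope| ≤ 0.2 SUL·min⁻¹. The sustained
("all subsequent windows") requirement means one quiet window on the inflow
shoulder cannot trigger, and a late re-acceleration retroactively removes
the plateau. The threshold is absolute, so detection is intentionally
scale-sensitive; with 1-minute frames 0.2 SUL·min⁻¹ equals SUL-per-frame.
Window length, threshold and the peak-skip are all configurable.

**Bladder onset.** The first mid-frame time at which bladder SUL ≥ 2×
background (gluteal muscle) SUL, with positive background. Reported at
mid-frame resolution without sub-frame interpolation, matching the
whole-minute resolution such studies report. Monotone in the factor.

**Stable vs rising.** A lesion is *stable* when a plateau is detected at or
before a 10-minute cutoff (stable lesions in the emulated setting settle by
~5–7 min, so 10 gives margin) and *rising* when no plateau is found. A
plateau detected after the cutoff is classified rising with a
`late_plateau` note: a trapping lesion whose late slope dips to the
threshold is still an accumulator, whereas genuinely reversible curves go
quiet well before the cutoff. This choice keeps the classifier's
ground-truth recovery exact (Ki = 0 ⇒ stable, Ki > 0 ⇒ rising) under noise
and between-subject variability; it is the one genuinely open design point
in the rule set, and the note makes such curves auditable.

## The phantom

The generator emulates the early pelvic kinetics of a ⁶⁸Ga-PSMA-11 bolus
study; all curves are produced in SUL units and converted to Bq/mL through
the scene's subject metadata.

* **Arterial input** — Feng-type bolus
  Cp(t) = (A1·Δt − A2 − A3)·e^(−λ1·Δt) + A2·e^(−λ2·Δt) + A3·e^(−λ3·Δt),
  Δt = t − τ, zero before the appearance delay τ and exactly zero at τ.
  Defaults (A1 = 13.8 SUL·min⁻², A2 = 5.34, A3 = 1.21 SUL, λ1 = 3.6,
  λ2 = 0.603, λ3 = 0.001 min⁻¹, τ = 0.05 min) were fitted by least squares
  so the 1-min-binned curve peaks ≈ 4.2 SUL in the first frame (continuous
  peak ≈ 5.2, inside the 3.6–5.4 SUL band typical of image-derived iliac
  inputs), crosses the 0.2 SUL/min slope threshold near 4.7 min (detector
  plateau at 4.5–5.5 min) and settles to ≈ 1.2 SUL.
* **Tissue** — one reversible compartment plus irreversible trapping:
  Ct = (1−vb)·[K1·∫Cp·e^(−k2(t−s))ds + Ki·∫Cp ds] + vb·Cp. Muscle
  (K1 = 0.32, k2 = 1.0 min⁻¹, vb = 0.04) shows a first-pass transient then
  a ≈ 0.4 SUL plateau with detector output 3.5 min. The stable lesion
  (K1 = 1.3, k2 = 0.8, Ki = 0) levels at ≈ 2 SUL; the rising lesion
  (K1 = 0.15, k2 = 0.5, Ki = 0.28 mL·mL⁻¹·min⁻¹) climbs for the whole scan
  with late slope ≈ 0.28 SUL/min, well clear of the plateau threshold so
  the stable/rising recovery is robust (400/400 correct over 20 seeded
  noisy cohorts), at the cost of a somewhat hotter 20-min value (≈ 8.5 SUL)
  than the ≈ 5 SUL a threshold-straddling lesion would show.
* **Bladder** — urine concentration kexc·∫_{t0}^t Cp / (Vb0 + inflow·(t−t0))
  with onset delay t0 = 8 min, clearance kexc = 60 mL/min (dimensionally a
  clearance: it multiplies an integral of concentration and is divided by a
  volume), initial urine volume 100 mL, inflow 1.5 mL/min; the
  twice-background rule then fires at 9.5 min on noiseless curves.
* **Numerics** — continuous curves are evaluated on a 0.01-min grid; the
  reversible compartment uses an exact-decay/trapezoidal-source stepping
  scheme (second-order, stable for any k2), trapping and bladder integrals
  use cumulative trapezoids. Frame values are duration-weighted averages of
  the fine-grid curve over each frame, matching how frame binning
  integrates counts — not instantaneous samples.
* **Noise** — Gaussian per frame (and per voxel in voxel mode) on the SUL
  scale with SD = α·√(max(c, ε)/Δt), the standard TAC-level surrogate for
  count statistics (variance ∝ concentration, ∝ 1/frame duration). Default
  α = 0.01, giving ~1–2 % relative noise on region-mean TACs, appropriate
  for multi-voxel ROIs on a modern digital scanner. Sinogram-level Poisson
  noise, scanner PSF, partial-volume effects and motion are *not* modeled,
  so passing tests demonstrate correctness of the quantification rules, not
  robustness to reconstruction artifacts.
* **Cohorts** — each subject multiplies every strictly positive rate or
  amplitude parameter by an independent lognormal factor (unit mean) with
  the between-subject CV (default 0.10, comparable to the inter-subject
  spread of arterial peak values such studies report); each visit applies
  further factors with the within-subject CV (default 0.05). Delays (τ,
  t0) and the blood volume fraction stay fixed. Lognormal keeps parameters
  positive; Ki = 0 stays exactly zero, so phenotype ground truth is
  preserved. Everything is bit-reproducible given the seed.
* **Voxel mode** — spheres (default: 0.64 mL artery, 12.3 mL muscle,
  2.05 mL stable lesion, 30.8 mL rising lesion — a ≈ 15× volume contrast —
  and a 17 mL bladder) on a 48×48×41 grid of 4-mm isotropic voxels, one bed
  position. Sphere centers sit between voxel centers so voxelized volumes
  track the analytic ones within ~5 %. Voxels carry the region's
  frame-averaged value plus noise; background is zero plus noise.
* **Decay** — the phantom emits decay-corrected concentrations (matching
  reconstructed images); an opt-in flag multiplies by
  e^(−ln2·t/67.71 min) for uncorrected output.

## Repeatability report

The per-region summary value is the maximum frame SUL over the scan
(configurable to a fixed-time SUL, since the basis of reported
test–retest percentages is often under-specified). Intra-patient change is
|x₂ − x₁|/D·100 with D = x₁ by default; D = mean(x₁, x₂) is selectable and
makes the measure symmetric under visit swap — the report records which
denominator was used. Inter-patient CoV uses the sample SD (n−1) over the
test-visit values. Group contrast reports per-group mean lesion volumes
raw and rounded to whole mL (the ratio is quoted on the rounded means, with
the raw ratio alongside), per-group mean SUL at requested times, and a
Welch two-sample t-test per time point; with one lesion per group the
p-value is reported as not computable rather than invented.

## Problem sizes and determinism

Default analyses use 30 × 1-min frames, 5-subject two-visit cohorts, and
20-cohort recovery sweeps; the full suite and the acceptance script each
run in well under a minute on one core. All randomness flows from
`numpy.random.default_rng(seed)`; fixed seed ⇒ bit-identical TACs, volumes
and CSV outputs.

## Known limitations

The compartmental construction is a *generative stand-in*, not a claim
about PSMA binding mechanism (receptor saturation vs perfusion limitation
is unresolved); recovered plateau times and classifications validate the
detectors, not tracer biology. The plateau rule's estimator, window, units
and persistence requirement are operational choices (kept configurable);
other choices shift detected plateau times by a frame or so. No DICOM or
list-mode input, no registration, no static whole-body workflow, no
kinetic-model fitting of measured data.
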