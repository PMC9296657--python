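# Methods

## Scope and assumptions

`natremri` models the quantitative analysis of a preclinical ²³Na-MRI study
of orthotopic breast tumours: magnitude sodium images normalised to a 50 mM
NaCl in-plane phantom, proton DWI for apparent diffusion coefficients,
region classification from the joint (sodium, ADC) feature space, ex vivo
calibration of intracellular and extracellular sodium, and the
two-compartment mixture model tying these together. Acquisition physics
(pulse sequences, k-space, relaxation) is out of scope throughout: images
enter the pipeline as magnitude voxel arrays with spacing metadata.

Two global assumptions shape the quantification:

- **Signal–concentration linearity.** The ²³Na signal is taken proportional
  to [NaCl]. Differential T1 saturation between phantom and tissue is not
  modelled, so "concentration" outputs are phantom-normalised signal on a
  mM scale rather than absolute tissue molarity. Longitudinal and
  between-region contrasts remain valid under any fixed scaling.
- **Shared geometry.** Sodium images, DWI volumes and ROI masks are assumed
  voxel-aligned on a common grid; no registration is performed. Coordinates
  are voxel-centred, 0-based, right-handed; a voxel centre sits at
  `index * spacing` mm.

## Synthetic study conditions

The `synth` module generates every input with known ground truth. Its
defaults are the study conditions used by the tests and the acceptance
script:

- **Sodium scene**: 48×48×24 grid at 1 mm isotropic; spherical 50 mM
  phantom of radius 4.1 mm (an 8.2 mm inner-diameter tube); ellipsoidal
  tumour (7×6×6 mm semi-axes) at a mean of 46.9 mM with smoothed Gaussian
  heterogeneity (SD 6 mM, 2-voxel smoothing — the spatial structure of
  intratumoural sodium is not characterised, so an isotropic correlated
  texture with free amplitude is used); background/non-tumour tissue at
  29.7 mM. Proportionality constant is 1 signal-unit/mM.
- **Coil gain**: volume mode is flat; surface mode applies
  g(x) = G/(d(x) + d₀)² with a floor d₀ = 2 mm avoiding the singularity on
  the coil plane, normalised to unit mean (receiver gain scale is
  arbitrary; unit-mean keeps `noise_sigma` on one scale across coil modes).
- **Noise**: Rician on magnitude images (|A + n₁ + i·n₂|, n ~ N(0, σ)),
  the physically appropriate model for magnitude MR; Gaussian on
  fluorescence (multiplicative, CV 2%) and voltages (additive, SD 0.3 mV).
- **DWI**: b = 0/100/300/700 s/mm², S₀ = 1000, tumour ADC 0.7×10⁻³ mm²/s
  (restricted diffusion) in a 1.8×10⁻³ background.
- **Cohorts**: bivariate normal (max normalised ²³Na, ADC) per class —
  tumour (1.9, 1.0×10⁻³), non-tumour (0.9, 1.5×10⁻³) with negative
  within-class cross-covariance. Spreads are chosen to give overlapping
  classes (single-feature LDA accuracy ≈ 80–90%), the regime in which the
  combined-vs-single-feature comparison is informative; the pooled Na–ADC
  correlation is negative by construction. The mean ²³Na signal is a fixed
  fraction (0.55) of the max with jitter — a free modelling choice, since
  only the joint (max, ADC) law is characterised.
- **SBFI**: per cell, a baseline phase at the resting [Na⁺]ᵢ (default
  25.9 mM) then ionophore-equilibrated plateaus at 10/20/50 mM; one-phase
  association with Y₀ = 1, Plateau = 2, K = 0.05 mM⁻¹ and 5% per-cell
  parameter scatter; 6 frames per phase.
- **Electrodes**: standards 48/96/144/192 mM, near-Nernstian response
  V = 58·log₁₀(C/144) mV, tissue recordings at 157.8 mM offset by a 10 mV
  junction potential; optional pre→post sensitivity drift. The generating
  response is deliberately *not* in the Padé(1,1) model class used for
  fitting, so calibration robustness to model mismatch is exercised
  (see Limitations).

What the generators do **not** emulate: partial-volume effects, motion,
spatially varying noise, T1/T2* contrast, dye leakage or photobleaching in
fluorescence, electrode hysteresis. Passing tests therefore demonstrate
correctness of the estimators under their stated models, not robustness to
every artefact of real acquisitions.

## Numerical choices

- **B1 correction** fits (log G, d₀) of the inverse-square field to a
  uniform concentrated-phantom reference by least squares in log-signal
  space (robust to the reference's large dynamic range; plain-space fitting
  by flag), bounds d₀ ∈ [0.1, 50] mm. The fitted gain map is normalised to
  unit mean, so correction preserves overall image scale and is invariant
  to the reference's intensity scale. A spatially flat reference cannot be
  represented by the model at finite d₀ and short-circuits to unit gain
  (exact identity). The max-signal statistic is computed on the corrected,
  unsmoothed image; an optional median filter is off by default because the
  max is noise-sensitive.
- **ADC fitting** uses ordinary least squares of ln S on b including b = 0,
  which reduces exactly to −ln(S/S₀)/b for two points; per-pair two-point
  ADCs are reported for audit. Voxels failing signal positivity (or an
  optional noise floor) are masked invalid rather than erroring. Scalar ADC
  only: no tensor, IVIM or kurtosis models.
- **LDA** uses class means, pooled within-class covariance with denominator
  n − 2, and class-frequency priors (equal priors by flag). Classes with a
  single sample contribute a mean and prior but no scatter, keeping LOOCV
  defined on very small cohorts; a pooled covariance with condition number
  above 10¹² is rejected as singular. Posterior ties break toward the
  larger prior, then toward the tumour class. Tumour is the positive class
  in every report.
- **ROC/AUC** sweeps all score thresholds; the trapezoidal area equals the
  Mann–Whitney pair-win fraction with ties counted ½.
- **PCA** defaults to correlation scaling (features have incommensurate
  units, phantom units vs mm²/s); loadings are signed so each component's
  first nonzero entry is positive. The 95% "concentration ellipse" is the
  Gaussian covariance ellipse (χ² quantile), one of several possible
  constructions, and is labelled as such.
- **One-phase-association fitting** uses deterministic multi-start least
  squares: Y₀/Plateau initialised from the data extremes and K swept over
  an 8-point log-spaced grid, best residual wins. The parameterisation
  Y₀ + (Plateau − Y₀)(1 − e^(−Kx)) is fixed so the baseline inversion is
  closed-form: x = −ln(1 − (F − Y₀)/(Plateau − Y₀))/K. Calibration is
  per-cell by default (matching the in-situ protocol's purpose of
  controlling cell-to-cell variation), with inverted baselines averaged per
  slice then across slices; a pooled-fit mode exists. Baselines at or below
  Y₀ return 0 mM with a warning; at or above Plateau they raise.
- **Padé(1,1) calibration** V(C) = (a + bC)/(1 + cC) is solved exactly for
  3 standards (linear system) and by nonlinear least squares from the
  linearised solution for more. Fits with a pole inside [40, 200] mM or a
  non-monotone curve over the standards are rejected. Inversion is the
  closed rational form C = (V′ − a)/(b − cV′) after junction-offset
  subtraction, and refuses to extrapolate outside the calibrated voltage
  range. V is fitted as a function of C (the C-on-V orientation differs
  only under noise). Sensitivity for drift QC is dV/dC at 120 mM; the pass
  boundary (5%) is inclusive with a float-round-off guard.
- **Compartment model** solutions outside the physical domain (EVF ∉ [0,1],
  negative concentrations) are returned with a `physiological=False` flag,
  never clipped — the two-compartment model omits blood and ductal spaces,
  so out-of-range solutions are diagnostically meaningful. Reported values
  follow the conventional precision (volume fractions 3 d.p.,
  concentrations 1 d.p.); full precision is kept internally.
- **Group statistics** use the pooled-variance Student t (Welch by flag)
  and the exact t-based Pearson p-value. "x-fold" is the relative change
  (A − B)/B — a documented convention, since ratio and relative-increase
  readings cannot be distinguished from usage alone.

## Problem sizes

The test suite and acceptance script run everything at desk scale: 48³-ish
image grids, cohorts of 32–400 rows, 50-replicate recovery studies at the
ex vivo sampling designs (3 slices × 11–16 cells for SBFI; 6 slices × 12
recordings for electrodes). These sizes give Monte-Carlo standard errors
well below the tolerances being checked while keeping the full suite under
a couple of minutes.

## Known limitations

- Concentration outputs inherit the linearity assumption; absolute mM
  values from real acquisitions would need T1 correction.
- The electrode calibration's Padé(1,1) form cannot represent a logarithmic
  response exactly: on the synthetic Nernstian electrode the inversion
  carries a deterministic ≈ −0.9 mM error at 157.8 mM (within its 2 mM
  recovery contract, and absent when the true response is rational). This
  is a property of the calibration model class, not of the fitter.
- LOOCV accuracy on label-shuffled data is slightly pessimistic relative to
  the majority rate (the held-out sample's removal shifts its own class
  mean away), a known small-sample property of cross-validation.
- The B1 model is a single-origin inverse-square field; real surface-coil
  profiles deviate at off-axis angles.
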