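# natremri

Quantitative analysis of preclinical sodium (²³Na) MRI in breast-cancer
models. Tissue sodium concentration is elevated in malignant breast lesions,
and combining ²³Na MRI with proton diffusion-weighted imaging (DWI) improves
non-invasive discrimination of tumour from healthy tissue. `natremri`
implements the full analysis chain as a tested, reusable Python library:

- **Sodium quantification** (`naquant`): surface-coil B1 correction by a
  fitted inverse-square gain field g(x) = G/(d(x) + d₀)², ROI statistics,
  and normalisation to an in-plane 50 mM NaCl phantom so that signal reads
  out as concentration (mM). Tumour volume by ROI voxel counting or the
  modified ellipsoid formula V = ½·L·W².
- **ADC mapping** (`dwiadc`): apparent diffusion coefficients from
  multi-b DWI series under the mono-exponential model S(b) = S₀·e^(−b·ADC),
  as the closed form −ln(S/S₀)/b for two b-values and a log-linear
  least-squares fit for more, at ROI and voxel level.
- **Classification** (`biomarker`): linear discriminant analysis (Gaussian
  classes, pooled covariance) built from first principles, leave-one-out
  cross-validation, independent test-set evaluation, ROC/AUC (trapezoid =
  Mann–Whitney pair fraction), confusion matrices, and PCA with loading
  vectors and concentration ellipses.
- **Ex vivo ion calibrations** (`ioncal`): SBFI fluorescence → intracellular
  [Na⁺] via one-phase-association fits, Y(x) = Y₀ + (Plateau − Y₀)(1 − e^(−Kx)),
  and closed-form baseline inversion; ion-selective electrode voltage →
  extracellular [Na⁺] via Padé(1,1) calibration V(C) = (a + bC)/(1 + cC),
  junction-offset subtraction, rational inversion, and pre/post sensitivity
  drift QC (5% tolerance).
- **Two-compartment model** (`compartment`): total = (1 − EVF)·[Na⁺]ᵢ +
  EVF·[Na⁺]ₑ with IVF = 1 − EVF, solved in all directions with
  physiology flags on out-of-range solutions.
- **Group statistics** (`report`): unpaired pooled-variance t tests,
  Pearson correlation, fold changes in the (A − B)/B convention.
- **Synthetic data** (`synth`): generators for every input — phantom/tumour
  sodium scenes with Rician noise and 1/r² coil falloff, DWI series, cohort
  feature tables, SBFI traces, electrode recordings — each with known
  ground truth, so the whole chain is testable without any acquisition.

Images are plain NumPy-backed `ImageVolume` objects with NIfTI round-trip
I/O (nibabel); tables are pandas DataFrames/CSV.

## Worked example

The two-compartment model resolves where tumour sodium accumulates. With
intracellular [Na⁺]ᵢ = 25.9 mM (SBFI), extracellular [Na⁺]ₑ = 157.8 mM
(electrodes) and total tissue [Na⁺] = 46.9 mM (ICP-MS):

```sh
$ python examples/compartment_model.py
tumour EVF = 0.159, IVF = 0.841
healthy gland [Na+]i = 5.4 mM (physiological: True)
forward check: total = 46.9 mM
```

An extracellular volume fraction of 0.159 means 84% of the tissue is
intracellular: the elevated total sodium must come from an intracellular
excess (25.9 mM vs the 5–15 mM healthy range), not from the extracellular
space. Re-solving at the same volume fractions for a healthy gland's total
(29.7 mM) returns 5.4 mM — squarely physiological.

The imaging side, end to end on synthetic data:

```sh
$ python examples/quantify_sodium_image.py
fitted coil gain floor d0 = 2.00 mm
phantom   : mean   50.0 mM  max   53.1 mM  (truth mean   50.0 mM, n=257)
tumour    : mean   51.6 mM  max   70.9 mM  (truth mean   51.5 mM, n=1039)
non_tumour: mean   29.7 mM  max   34.6 mM  (truth mean   29.7 mM, n=980)
```

The remaining examples (`adc_mapping.py`, `classify_regions.py`,
`ion_calibrations.py`, `group_statistics.py`) each run one capability on a
small synthetic input and print what the numbers mean.

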