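"""Map the apparent diffusion coefficient from a multi-b DWI series.

Simulates mono-exponential diffusion decay S(b) = S0 exp(-b ADC) at
b = 0/100/300/700 s/mm^2 with Rician noise, fits the log-linear model per
voxel and per ROI, and compares against the generating truth. Low tumour
ADC reflects restricted water diffusion in densely cellular tissue.
"""

import numpy as np

from natremri import dwiadc, synth

spec = synth.DWISceneSpec(noise_sigma=10.0, seed=7)
series, truth_map, tumour = synth.generate_dwi_series(spec)

roi = dwiadc.compute_adc_roi(series, tumour)
print(f"tumour ROI ADC = {roi.adc:.3e} mm^2/s (truth {spec.adc_tumour:.3e})")
print("per-pair two-point ADCs:", {b: f"{v:.3e}" for b, v in roi.pairwise_adc.items()})

amap = dwiadc.compute_adc_map(series)
est = dwiadc.summarise_adc_map(amap, tumour)
err = np.nanmedian(np.abs(amap.adc[tumour] - truth_map[tumour]) / truth_map[tumour])
print(f"voxelwise map: tumour mean {est:.3e} mm^2/s, median |error| {100 * err:.1f}%")
print(f"invalid voxel fraction: {amap.invalid_fraction:.3f}")
# ROI-level fitting of the mean signal is far less noisy than single-voxel
# fits; the pairwise ADCs audit consistency across b-value pairs.
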