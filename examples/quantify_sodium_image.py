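"""Quantify a sodium image: simulate a surface-coil scene, correct the B1
field, and report phantom-normalised ROI concentrations.

The scene holds a 50 mM NaCl reference phantom, a tumour with elevated
heterogeneous sodium, and baseline non-tumour tissue, imaged through a
surface coil whose receive gain falls off as 1/r^2. The pipeline fits the
gain from a uniform 1 M phantom reference, divides it out, and normalises
ROI statistics by the phantom so signal becomes concentration (mM).
"""

from natremri import naquant, synth

spec = synth.ScenePhantomSpec(coil_mode="surface", noise_sigma=1.5, seed=42)
image, rois, truth = synth.generate_sodium_image(spec)
reference = synth.generate_b1_reference(spec)

corrected, field = naquant.b1_correct(image, reference, spec.coil_origin)
stats = naquant.normalize_to_phantom(naquant.roi_stats(corrected, rois))

print(f"fitted coil gain floor d0 = {field.d0:.2f} mm")
for name in ("phantom", "tumour", "non_tumour"):
    s = stats[name]
    print(
        f"{name:10s}: mean {s.mean_mM:6.1f} mM  max {s.max_mM:6.1f} mM  "
        f"(truth mean {truth[rois[name]].mean():6.1f} mM, n={s.n_vox})"
    )
# The phantom self-normalises to 50 mM; tumour sits well above the
# non-tumour baseline, and the estimates track the generating truth.
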