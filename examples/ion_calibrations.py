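"""Recover intracellular and extracellular sodium from ex vivo recordings.

SBFI fluorescence: per-cell plateaus at 10/20/50 mM calibration steps are
fitted with a one-phase association and each cell's baseline fluorescence
is inverted to its resting [Na+]i. Ion-selective electrode: standards at
48/96/144/192 mM are fitted with a Padé(1,1) approximant, the junction
offset is subtracted from tissue recordings, and voltages are inverted to
[Na+]e, with a pre/post sensitivity drift check.
"""

import numpy as np

from natremri import ioncal, synth

# --- SBFI: 3 slices, 11-16 cells each, truth 25.9 mM
rng = np.random.default_rng(0)
slice_means = []
for s in range(3):
    n = int(rng.integers(11, 17))
    traces = synth.generate_sbfi_traces(
        synth.SBFITraceSpec(n_cells=n, seed=int(rng.integers(2**31)))
    )
    result = ioncal.recover_nai_from_traces(traces)
    slice_means.append(result["nai_mM"].mean())
    print(f"slice {s}: {n} cells, mean [Na+]i = {slice_means[-1]:.1f} mM")
print(f"resting [Na+]i = {np.mean(slice_means):.1f} mM (truth 25.9)")

# --- ISME: 6 slices, 12 recordings each, truth 157.8 mM
slice_means = []
for s in range(6):
    spec = synth.ISMERecordingSpec(seed=int(rng.integers(2**31)),
                                   sensitivity_drift_fraction=0.02)
    rec = synth.generate_isme_recordings(spec)
    out = ioncal.recover_nae_from_recordings(
        rec["standards"], rec["tissue"], junction_offset=spec.junction_offset
    )
    slice_means.append(out["nae_mM"]["nae_mM"].mean())
print(
    f"tissue [Na+]e = {np.mean(slice_means):.1f} mM (truth 157.8), "
    f"last-slice drift {100 * out['drift']:.1f}% (pass: {out['drift_pass']})"
)
# [Na+]i well above the healthy 5-15 mM range, with [Na+]e in the normal
# serum range, locates the tumour's sodium excess inside the cells.
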