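"""Resolve tissue volume fractions from the two-compartment sodium model.

Given intracellular sodium measured by SBFI fluorescence (25.9 mM),
extracellular sodium from ion-selective microelectrodes (157.8 mM) and the
total tissue sodium from ICP-MS (46.9 mM), the mixture identity
total = (1 - EVF) * Nai + EVF * Nae resolves the extracellular and
intracellular volume fractions; re-solving for a healthy gland's total
(29.7 mM) at the same volume fractions returns its intracellular sodium.
"""

from natremri import forward_total, solve_evf, solve_nai

tumour = solve_evf(total=46.9, nai=25.9, nae=157.8)
print(f"tumour EVF = {tumour.evf:.3f}, IVF = {tumour.ivf:.3f}")

gland = solve_nai(total=29.7, evf=tumour.evf, nae=158.0)
print(f"healthy gland [Na+]i = {gland.nai:.1f} mM (physiological: {gland.physiological})")

back = forward_total(nai=25.9, nae=157.8, evf=tumour.evf)
print(f"forward check: total = {back:.1f} mM")

# An EVF of ~0.16 says the elevated tumour sodium must come from the
# intracellular compartment: a healthy-range EVF cannot produce 46.9 mM
# total unless [Na+]i is far above the normal 5-15 mM.
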