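"""Classify tumour vs non-tumour regions from sodium and diffusion features.

Trains linear discriminant models on a synthetic cohort of (maximum
phantom-normalised sodium signal, ADC) feature pairs, evaluates with
leave-one-out cross-validation and on an independent test cohort, and
compares single-feature models against the combined two-feature model.
"""

from natremri import biomarker as bm
from natremri import synth

train = synth.generate_cohort(synth.CohortSpec(seed=1))
test = synth.generate_cohort(synth.CohortSpec(seed=2))

for feats in (["max_na_norm"], ["adc"], ["max_na_norm", "adc"]):
    model = bm.fit_lda(train, feats)
    cv = bm.loocv(train, feats)
    rep = bm.evaluate_on_test(model, test)
    print(
        f"{'+'.join(feats):22s} LOOCV {100 * cv.accuracy:5.1f}%  "
        f"test {100 * rep.accuracy:5.1f}%  sens {rep.sensitivity:.2f}  "
        f"spec {rep.specificity:.2f}  AUC {rep.auc:.2f}"
    )

res = bm.pca(train, ["max_na_norm", "adc"])
print(
    "PCA: PC1 explains "
    f"{100 * res.explained_variance_ratio[0]:.1f}% of variance; "
    f"loadings {res.loadings[:, 0].round(3)} (opposing signs = anti-correlated)"
)
# The combined model is typically at least as accurate as either single
# feature: sodium accumulation and restricted diffusion carry overlapping
# but not identical information about malignancy.
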