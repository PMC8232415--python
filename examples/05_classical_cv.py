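"""Classical route end to end: cohort -> images -> tCENTRIST -> PCA ->
classifier bank -> ten-fold cross-validated metrics.

Pooled accuracy/sensitivity/specificity are percentages over all folds'
confusion counts; F1 and AUC are 0-1. On this separable cohort the linear
classifiers should land in the 90s; rerun with `es.null_spec` (and
grouping="subject") to watch everything collapse to chance.
"""

import eegspect as es

recs = es.generate_cohort(es.separable_spec(subjects_per_class=4, duration=30, seed=17))
images = es.images_from_cohort(recs)
fset = es.features_from_images(images)
print(f"{len(fset)} images x {fset.features.shape[1]} features\n")

plan = es.make_folds(fset, k=10, seed=17)
print(f"{'clf':5s} {'acc%':>7s} {'sens%':>7s} {'spec%':>7s} {'F1':>6s} {'AUC':>6s}")
for name in ("nb", "lda", "knn", "lr", "svm"):
    rep = es.cross_validate(fset, name, plan=plan, seed=17)
    print(f"{name:5s} {rep.accuracy:7.2f} {rep.sensitivity:7.2f} "
          f"{rep.specificity:7.2f} {rep.f1:6.3f} {rep.auc:6.3f}")
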