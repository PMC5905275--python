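"""Train the sweet/bitter Random Forest and evaluate it both ways.

Builds a synthetic two-class molecule set (300 per class, each class
enriched for its own substructure motif at 90% purity), splits it
80/20 with stratification, cross-validates on the training portion and
validates on the held-out portion — the same protocol used for real
taste data.
"""

from tasteforest import FixtureSpec, RFConfig, generate_labeled_set, kfold_cv, predict, stratified_split, train
from tasteforest.metrics import dual_report
from tasteforest.model import cv_report

records = generate_labeled_set(FixtureSpec(n_per_class=300, motif_purity=0.9, seed=1))
train_set, test_set = stratified_split(records, test_fraction=0.2, seed=1)
config = RFConfig(n_trees=1000, seed=1)

cv = cv_report(train_set, kfold_cv(train_set, config, k=10))["sweet"]
model = train(train_set, config)
preds = predict(model, test_set)
ext = dual_report([r.label for r in test_set], [p.predicted_class for p in preds],
                  [p.class_scores["sweet"] for p in preds])["sweet"]

print(f"{'':>20} {'Accuracy(%)':>12} {'ROC-AUC':>8} {'Sens':>6} {'Spec':>6} {'Kappa':>6}")
for name, r in (("Cross-validation", cv), ("External validation", ext)):
    print(f"{name:>20} {100 * r.accuracy:>12.2f} {r.roc_auc:>8.3f} "
          f"{r.sensitivity:>6.2f} {r.specificity:>6.2f} {r.cohens_kappa:>6.2f}")

# Accuracy ~90% and AUC ~0.97 are the ceiling the 0.9 motif purity allows:
# about 10% of molecules carry the wrong-class motif and are genuinely
# ambiguous. Kappa near 0.8 means agreement far beyond chance.
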