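"""Train and compare the three separation-mode classifiers.

Generates a seeded 66-run dataset whose outlet distributions are
separable by mode (zigzag / mixed / bumped), trains complement naive
Bayes, KNN and SVM-RBF under stratified 5-fold cross-validation, and
prints each family's per-split accuracies plus the best model's
classification report.
"""

from dldflow.mode_ml import FAMILIES, evaluate, predict_mode, train_model
from dldflow.synthetic import generate_mode_dataset

ds = generate_mode_dataset(n_records=66, class_balance="balanced",
                           noise_sd=0.0, seed=7)
print(f"dataset: {len(ds)} runs, features {ds.feature_matrix.shape}")

best = None
for family in FAMILIES:
    model = train_model(ds, family, folds=5, seed=7)
    accs = ", ".join(f"{a:.2f}" for a in model.split_accuracies)
    extra = f", k={model.chosen_k}" if model.chosen_k else ""
    print(f"{family:8s} split accuracies: [{accs}]{extra}")
    if family == "CNB":
        best = model

report = evaluate(best, [ds.records[i] for i in best.best_split_test_idx])
print("\nbest CNB model on its held-out fold:")
print(report)

# A fresh run concentrated in the top outlets with 20 um particles is
# above the critical diameter -> bumped mode.
mode = predict_mode(best, flow_rate=2.0, particle_size=20.0,
                    distribution=[0.4, 0.3, 0.2, 0.1] + [0.0] * 8)
print(f"\npredicted mode for a top-outlet 20 um run: {mode}")
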