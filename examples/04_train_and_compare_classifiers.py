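"""Train the MLP and the LDA baseline on top-5 t-ranked features.

The feed-forward perceptron has one hidden layer of five sigmoid units
and a sigmoid output, trained by full-batch gradient descent on the mean
cross-entropy; LDA is the shared-covariance Gaussian maximum-posterior
rule.  Selection happens on the training half only, so the held-out
metrics are leakage-free.
"""

import numpy as np

from seldiclass import (
    TrainConfig, confusion, default_paper_like_config, generate, predict,
    rank_features, split, train_lda, train_mlp,
)

cohort, _ = generate(default_paper_like_config(seed=1))
plan = split(cohort.sample_ids, fraction=0.8, seed=2)
train_half, test_half = cohort.subset(plan.train_ids), cohort.subset(plan.test_ids)
print(f"split: {len(plan.train_ids)} training / {len(plan.test_ids)} test samples")

idx = list(rank_features(train_half).top(5))
x_train = train_half.intensity_matrix()[:, idx]
x_test = test_half.intensity_matrix()[:, idx]
print(f"selected m/z: {[round(float(cohort.grid.values[i]), 1) for i in idx]}")

mlp, losses = train_mlp(x_train, train_half.label_array(), TrainConfig(seed=3))
lda = train_lda(x_train, train_half.label_array())
print(f"MLP cross-entropy: {losses[0]:.4f} -> {losses[-1]:.4f} over {len(losses)} epochs")

for name, model in (("MLP", mlp), ("LDA", lda)):
    pred, _ = predict(model, x_test)
    report = confusion(list(test_half.label_array()), list(pred))
    print(f"{name}: accuracy {report.accuracy_pct:.2f}% | "
          f"sensitivity {report.sensitivity:.3f} | specificity {report.specificity:.3f}")
# accuracy = 100*(1 - errors/total); sensitivity is the fraction of cancers
# flagged, specificity the fraction of controls cleared, on the unseen 20%.
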