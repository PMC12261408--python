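"""Robustness to corrupted training labels.

Hides a fraction of known positives among the training negatives (false
negatives) or injects unverified positives (false positives), then measures
how far the cross-validated AUROC moves. Test labels are never perturbed.
"""

from atcpred import (
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    atc_similarity_matrix,
    build_similarity_matrix,
    generate_corpus,
    robustness_study,
)

corpus = generate_corpus(SyntheticConfig(n_drugs=120, branching=(3, 2, 2, 2), seed=5))
table = corpus.truth[2]
sims = {c: build_similarity_matrix(corpus.drugs, c) for c in ("CS", "DDI", "SE")}
atc = atc_similarity_matrix(table.code_labels, "whs", 2).values

model_cfg = ModelConfig(model_width=32, n_heads=4, n_blocks=2, ffn_hidden=64,
                        dropout=0.1, seed=1)
train_cfg = TrainConfig(epochs=20, batch_size=32, learning_rate=1e-3, seed=1)

results = robustness_study([-0.2, 0.0, 0.2], table, sims, atc, model_cfg, train_cfg,
                           n_folds=3, seed=1)
print("training-label perturbation sweep (3-fold CV):")
for r in results:
    print(f"  {r.tag:>9}: AUROC {r.mean_auroc:.3f} +/- {r.sd_auroc:.3f}")
print("A robust model keeps its AUROC nearly flat across the sweep: the masked")
print("association features and balanced sampling limit the damage a corrupted")
print("training label can do.")
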