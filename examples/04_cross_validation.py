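"""Cross-validated prediction on a small synthetic corpus.

Runs the full pipeline — balanced negative sampling, stratified folds,
leakage-masked feature aggregation, convolution-transformer training — and
reports AUROC/AUPRC as mean +/- sd over folds. Uses a reduced model so the
example finishes in about a minute.
"""

from atcpred import (
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    atc_similarity_matrix,
    build_similarity_matrix,
    cross_validate,
    generate_corpus,
)

corpus = generate_corpus(SyntheticConfig(n_drugs=120, branching=(3, 2, 2, 2), seed=5))
level = 2
table = corpus.truth[level]
sims = {c: build_similarity_matrix(corpus.drugs, c) for c in ("CS", "DDI", "SE")}
atc = atc_similarity_matrix(table.code_labels, "whs", level).values

model_cfg = ModelConfig(model_width=32, n_heads=4, n_blocks=2, ffn_hidden=64,
                        dropout=0.1, seed=1)
train_cfg = TrainConfig(epochs=20, batch_size=32, learning_rate=1e-3, seed=1)

result = cross_validate(table, sims, atc, model_cfg, train_cfg, n_folds=3, seed=1)
print(f"level-{level} prediction over {len(result.fold_auroc)} folds:")
print(f"  AUROC {result.mean_auroc:.3f} +/- {result.sd_auroc:.3f}")
print(f"  AUPRC {result.mean_auprc:.3f} +/- {result.sd_auprc:.3f}")
print("Values near 1 mean held-out drug-code pairs are ranked almost perfectly;")
print("0.5 would be chance level.")
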