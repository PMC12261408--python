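# atcpred

Predicting Anatomical Therapeutic Chemical (ATC) classification codes for
drugs. A drug's ATC codes summarise where it acts and what it does; a code a
drug *should* carry but does not yet is a drug-repositioning hypothesis.
`atcpred` frames the problem as binary link prediction on drug–code pairs
and is aimed at computational pharmacology researchers who have drug feature
files (fingerprints or SMILES, interaction lists, side-effect lists) and a
drug–ATC association table, and want calibrated rankings of candidate pairs
at any of ATC levels 1–4.

## The method

Three drug–drug similarity channels are built as intersection-over-union on
sets: **CS** (Tanimoto on 1024-bit circular fingerprints), **DDI** (Jaccard
on interaction-partner sets) and **SE** (Jaccard on side-effect sets).

Codes are compared with the **weighted-hierarchical similarity (WHS)**. With
S_k(a) the set of a code's prefixes down to level k and
N_k(a,b) = |S_k(a) ∩ S_k(b)| the shared-prefix depth,

    WHS_k(a, b) = (2·W_k^{N_k(a,b)} + k²) / (2·W_k^k + k²),
    W_k^n = Σ_{i=0}^{n−1} (k − i)²,

so disagreement near the root of the hierarchy is penalised quadratically
harder than disagreement at the leaves. Two simpler measures are included
for comparison: the uniform-weight RNPSim_k = (2·N_k + 1)/(2k + 1) and the
inverse-frequency NPSim(a,b) = w(a)·w(b)·exp(−0.25·d(a,b)).

For a candidate pair (drug d, code a) each channel contributes a
2 × (n + m_k) feature matrix whose aligned rows hold, over the same column
grid, the masked association row of d and its drug-similarity row, and the
WHS row of a and its masked association column. Masking zeroes the cells of
the current fold's test pairs and the target pair itself, so the model never
sees the label it predicts. Each channel's matrix passes through a
**convolution–transformer encoder** — a 1-D convolution tokeniser, stacked
transformer encoder blocks with multi-head scaled dot-product attention
(softmax(QKᵀ/√d_k)V) and a ReLU feed-forward network, then average pooling —
and the channel embeddings are concatenated into a fully connected layer
with a sigmoid that outputs the association probability. Training is binary
cross-entropy with Adam on a balanced set (all known positives plus an equal
number of sampled negatives), evaluated by stratified 10-fold
cross-validation with AUROC and AUPRC reported as mean ± sd over folds.

The neural model runs on a compact numpy reverse-mode autodiff core shipped
with the package (`atcpred.nn`); no deep-learning framework is required.

## Worked example

```python
from atcpred import parse_atc_code, shared_levels, whs, rnp_sim

a, b = parse_atc_code("A03AA", 4), parse_atc_code("A03BB", 4)
print(list(a.prefixes))          # ['A', 'A03', 'A03A', 'A03AA']
print(shared_levels(a, b, 4))    # 2   -- they agree through level 2
print(round(whs(a, b, 4), 4))    # 0.8684
print(round(rnp_sim(a, b, 4), 4))# 0.5556
```

The two codes share their anatomical group (A) and therapeutic subgroup
(A03) but split at level 3. WHS keeps their similarity high (0.8684) because
the expensive low levels agree; the uniform-weight measure is far stricter
(0.5556). At level 1 the two measures coincide exactly.

End-to-end on synthetic data (`python examples/04_cross_validation.py`,
about 20 s):

```
level-2 prediction over 3 folds:
  AUROC 0.988 +/- 0.010
  AUPRC 0.990 +/- 0.008
```

The generator plants within-branch sharing of fingerprint bits, interaction
partners and side effects, and the model recovers the held-out drug–code
associations almost perfectly; a permuted-label control sits at chance
(≈ 0.5). The other scripts in `examples/` walk through each capability:
ATC similarity, the three channels, corpus generation, and the label-noise
robustness sweep.

A command-line interface wraps the same pipeline:

```bash
atcpred simulate --seed 1 --out corpus/
atcpred similarities --associations corpus/associations.tsv \
    --fingerprints corpus/fingerprints.tsv --level 2 --atc-measure whs --out sims/
atcpred evaluate --associations corpus/associations.tsv \
    --fingerprints corpus/fingerprints.tsv --ddi corpus/ddi.tsv \
    --se corpus/side_effects.tsv --level 2 --folds 5 --seed 1 --out results/
```

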