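# Methods

## Problem setting

Given n drugs, the m_k distinct ATC codes at level k (k = 1..4), and a
binary association table Y ∈ {0,1}^{n×m_k}, the task is to score unseen
(drug, code) cells. The working assumption — shared by the family of
similarity-based ATC predictors — is guilt by association: drugs that look
alike (structurally, pharmacologically, clinically) tend to carry nearby
codes, and codes that sit close in the hierarchy tend to annotate similar
drugs. Level 5 of the ATC system is out of scope: it enumerates individual
substances, so there is no class structure to generalise over.

## Similarity channels

Drug similarity is intersection-over-union on three feature sets per drug:
fingerprint bits (Tanimoto; 1024-bit circular fingerprints, radius 2 when
derived from SMILES via the optional rdkit adapter — the radius is our
choice, the width is the method's standard), interaction-partner sets and
side-effect sets (Jaccard). A drug with an empty feature set has similarity
0 to everything *including itself*: an empty record is absence of evidence,
and pretending self-similarity would inject a spurious unit diagonal into
the model input. Interaction types and directions are deliberately ignored;
the partner-set formulation uses only who interacts with whom.

Code similarity is the weighted-hierarchical similarity (WHS)

    WHS_k(a,b) = (2·W_k^{N_k(a,b)} + k²) / (2·W_k^k + k²),   W_k^n = Σ_{i<n} (k−i)²,

where N_k is the shared-prefix depth. The weight increments (k−n)² shrink as
agreement deepens, encoding that a split at the anatomical level separates
codes far more than a split between chemical subgroups. The k² smoothing
term keeps the similarity positive even for fully disjoint codes. We read
the weight term as W_k evaluated *at* N_k (a superscript application): the
cumulative-weight function is otherwise pointless, and only this reading
makes WHS collapse to the uniform-weight RNPSim at level 1, an identity the
package asserts exactly. The value WHS₄(A03AA, A03BB) = 66/76 ≈ 0.8684 is
regression-locked as this package's derivation.

Two comparison measures are provided. RNPSim_k = (2N_k+1)/(2k+1) weights all
levels equally. NPSim(a,b) = w(a)·w(b)·exp(−0.25·d(a,b)) weights codes by
the inverse of their positive-sample frequency; its distance d is not pinned
down in the literature we follow, so we fix the canonical tree distance
d = 2·(k − N_k) (edges through the deepest common ancestor), which gives
d = 0 and hence exp(0) = 1 for identical codes. NPSim is *not* renormalised
to [0,1]: rare codes get weights above 1 by construction, and we document
the property rather than distort the formula. Frequencies are estimated from
training pairs only; estimating them on the full dataset would leak label
information into the kernel.

## Masked association features

Each candidate pair (d, a) and channel c yields a 2 × (n + m_k) matrix:

    row 0: [ Y*(d, ·)  over codes | S_c(d, ·) over drugs ]
    row 1: [ WHS(a, ·) over codes | Y*(·, a)  over drugs ]

with Y* a masked copy of Y in which every test-pair cell of the current fold
and the target cell (d, a) itself are zeroed. Masking is the load-bearing
design: row 0 and row 1 both contain the target cell, and without zeroing it
the model would be handed its own label. The two rows are column-aligned —
drug-block column i is drug i in both rows — so a convolution kernel sliding
along the columns sees the pair (similarity of d to drug i, whether drug i
carries a), exactly the evidence the guilt-by-association assumption needs.
Block order within a row ([codes | drugs]) is a fixed convention of this
package, locked because the column grids of the two rows must align.
Similarity diagonals (sim(d,d) = 1, WHS(a,a) = 1) are left untouched: only
associations are labels; similarities are inputs.

Masking is copy-on-write (the source table is never modified), and a test
instrumentation hook (`features.leakage_audit`) asserts during feature
assembly that every audited cell really reads zero.

## The encoder and head

Each channel's feature matrix is encoded independently:

1. **Convolution tokeniser.** A 1-D convolution treats the 2 rows as input
   channels (kernel 16, stride 8, 128 output channels by default), producing
   L = ⌊(n + m_k − 16)/8⌋ + 1 tokens. The geometry is this package's choice,
   sized so that the ~3.5k columns of a level-4 problem become a
   transformer-friendly token count; all three numbers are config-exposed.
2. **Sinusoidal positional encoding** (optional; `none` preserves a purely
   attention-based reading). Which variant is right is genuinely open; we
   default to sinusoidal because the token index carries block identity.
3. **Transformer blocks.** n_blocks post-norm encoder blocks: multi-head
   scaled dot-product self-attention (softmax(QKᵀ/√d_k)V per head, heads
   concatenated) and a two-layer ReLU feed-forward network, residual
   connections, layer normalisation and dropout. Post-norm with ReLU is our
   concrete instantiation of an architecture stated only loosely in the
   source method.
4. **Average pooling** over tokens gives the channel embedding.

The per-channel embeddings are concatenated in fixed channel order and a
single fully connected layer plus sigmoid yields the probability. The head
is therefore channel-position-aware: permuting channel inputs changes the
output. One encoder per channel is the default (three weight sets,
mirroring the three parallel branches of the architecture); a shared-weights
option exists for ablation.

Defaults dropout 0.1, 16 heads, feed-forward width 128 and 3 blocks follow
the configuration the underlying study found optimal. The optimisation
hyperparameters (binary cross-entropy, Adam, epochs 50, batch 32, learning
rate 1e-4) are this package's defaults — the study defers its exact training
setup to supplementary material we do not rely on — and every one of them is
config-exposed. Training aborts with a diagnostic if the loss becomes
non-finite.

The whole network runs on a small reverse-mode autodiff core over numpy
(`atcpred.nn`): broadcast-aware elementwise ops, batched matmul, softmax,
layer norm, and a numerically stable BCE-with-logits loss. Its gradients are
verified against central differences in the test suite (relative error
< 1e-5 on all non-negligible components of a two-block model).

## Data handling

Negative sampling draws, once per level and seed, as many distinct zero
cells as there are positives — balanced classes, sampled before fold
splitting because the balanced set is what cross-validation then partitions.
Folds are stratified by label (the source protocol says only "ten folds";
stratification prevents degenerate folds at small n and changes nothing in
expectation). Per-fold metrics are computed on that fold's test pairs only —
no score pooling — and summarised as mean ± sample sd (ddof = 1).

Robustness experiments corrupt *training* labels only, after fold splitting:
`false_negative` relabels ⌊fraction·P⌋ known positives as 0, `false_positive`
adds ⌊fraction·P⌋ unused zero cells labelled 1. The association table used
for features is left as-is; only the supervision changes, matching the
scenario of annotation errors in the training labels.

## Synthetic corpus

The generator plants the structure the method exploits, with everything a
deterministic function of the config:

* a 4-level prefix tree with ATC-format labels (default branching 4/3/2/2 =
  48 leaves), each drug assigned one uniform leaf plus a second with
  probability 0.1 (drugs carry multiple codes in reality);
* fingerprints: every tree node owns a random bit pool (32 shared bits per
  ancestor chain, split 8 per level) and a drug's fingerprint is the union
  of its chain's pools plus background bits at rate 0.01 — so structural
  similarity decays with tree distance, the gradient WHS is built to track;
* interactions: within-level-2-branch edge probability 0.3 versus 0.01
  background (partner sets are symmetric by construction);
* side effects: each level-2 branch owns a 15-effect pool sampled at rate
  0.7 per drug, over ~2 background effects per drug.

Defaults (200 drugs, 32 shared bits, 0.3 within-branch interaction
probability) are the package's standard test conditions. Generation-time
label noise only deletes associations (missing annotations — the realistic
direction) and never orphans a drug; spurious positives are the robustness
module's job. Truth tables at different levels are consistent under prefix
truncation by construction (asserted at zero noise).

What the corpus does *not* emulate: real fingerprint marginals and
correlated substructures, degree-heterogeneous interaction networks,
frequency-skewed side-effect vocabularies, and non-uniform code occupancy.
Passing the planted-signal tests therefore shows the pipeline can recover a
clean hierarchical signal end-to-end without leakage — not that it matches
any particular performance level on licensed pharmacological databases,
which this package does not ship.

## Experiment scales and numerical choices

The heavier checks run a reduced model (width 32, 4 heads, 2 blocks, 20
epochs, learning rate 1e-3, 5 folds) on the 200-drug corpus at level 2 —
the smallest level with a non-trivial code set — where it reaches mean AUROC
≈ 0.99 against a permuted-label control at ≈ 0.5, and ±20% training-label
corruption moves mean AUROC by well under 0.05. AUROC uses the Mann–Whitney
convention (ties = ½, computed via average ranks); AUPRC is the step-curve
area with operating points at the last element of each tied-score run — both
conventions are pinned by regression tests against brute-force oracles.
Softmax subtracts the row max; BCE works on logits via logaddexp; sigmoid is
evaluated piecewise; Adam uses (0.9, 0.999, 1e-8).

## Known limitations

* Cold start: a drug with no known associations yields an all-zero
  association row, and per-drug (leave-drug-out) splitting is not provided.
* Sampled negatives may be unobserved positives; the robustness results
  bound, but do not remove, the effect.
* The CS channel sees 2-D fingerprints only; 3-D structure is out of scope.
* Pure-numpy training is single-threaded per matmul chunk and intended for
  corpora up to a few thousand drugs, not for GPU-scale workloads.
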