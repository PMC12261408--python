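"""Generate a synthetic corpus with planted within-branch structure.

Drugs assigned to the same branch of the code tree share fingerprint bits,
interaction partners and side effects, so all three similarity channels
carry signal about the true codes — the structure the predictor must recover.
"""

import tempfile
from pathlib import Path

from atcpred import SyntheticConfig, generate_corpus, planted_signal_strength, write_corpus

config = SyntheticConfig(n_drugs=100, branching=(4, 3, 2, 2), seed=42)
corpus = generate_corpus(config)

print(f"{len(corpus.drugs)} drugs over {len(corpus.codes[4])} occupied leaf codes")
for level in (1, 2, 3, 4):
    t = corpus.truth[level]
    print(f"  level {level}: {t.n_codes:3d} codes, {int(t.matrix.sum())} positive associations")

print("\nPlanted signal (mean within-group minus between-group similarity, level 2):")
for channel in ("CS", "DDI", "SE"):
    print(f"  {channel}: {planted_signal_strength(corpus, channel):.3f}")
print("Positive values mean drugs sharing a code look more alike in that channel.")

out = Path(tempfile.mkdtemp()) / "corpus"
paths = write_corpus(corpus, out)
print(f"\nwrote {', '.join(p.name for p in paths.values())} to {out}")
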