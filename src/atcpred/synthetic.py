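"""Seed-reproducible synthetic corpora with planted, tunable signal.

The generator emulates the structure the predictor exploits in real data:
drugs that sit in the same branch of the classification tree tend to share
chemical substructure, interaction partners and side effects.  Concretely:

* a fixed-depth 4-level prefix tree of ATC-format labels (``A``, ``A01``,
  ``A01A``, ``A01AA`` ...) with configurable branching per level;
* each drug is assigned a leaf uniformly at random (plus, with probability
  ``multi_code_rate``, a second random leaf — drugs may carry several codes);
* fingerprints: every tree node owns a random bit pool; a drug's fingerprint
  is the union of the pools along its leaf's ancestor chain (signal that
  decays with tree distance, mirroring the hierarchy) plus background bits;
* interactions: drug pairs in the same level-2 branch are connected with a
  high probability, all other pairs with a low background probability;
* side effects: each level-2 branch owns a side-effect pool that its drugs
  sample from, on top of background side effects.

Associations at each level are the drug's true codes truncated to that
level; optional label noise deletes known associations (the
missing-annotation failure mode; spurious 0->1 corruption is the job of
``dataset.inject_label_noise``).  Everything is a deterministic function of
the config, including the seed.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .atc import AtcCode, parse_atc_code
from .dataset import AssociationTable, build_association_table
from .drug_similarity import CHANNELS, DrugRecord, build_similarity_matrix
from .errors import ValidationError

__all__ = [
    "SyntheticConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "planted_signal_strength",
    "write_corpus",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults define the package's standard test corpus."""

    n_drugs: int = 200
    branching: tuple[int, int, int, int] = (4, 3, 2, 2)
    fingerprint_bits: int = 1024
    shared_bits_per_branch: int = 32  # split evenly across the 4 ancestor pools
    background_bit_rate: float = 0.01
    within_branch_ddi_prob: float = 0.3
    background_ddi_prob: float = 0.01
    branch_se_pool_size: int = 15
    se_inclusion_rate: float = 0.7
    background_se_rate: float = 0.01
    background_se_vocab: int = 200
    label_noise_rate: float = 0.0
    multi_code_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ValidationError("n_drugs must be >= 1")
        if len(self.branching) != 4 or any(b < 1 for b in self.branching):
            raise ValidationError("branching must give >= 1 children at each of 4 levels")
        if self.branching[0] > 26 or self.branching[2] > 26 or self.branching[3] > 26:
            raise ValidationError("letter-coded levels support at most 26 children")
        if self.branching[1] > 99:
            raise ValidationError("digit-coded level supports at most 99 children")
        for name in ("background_bit_rate", "within_branch_ddi_prob", "background_ddi_prob",
                     "se_inclusion_rate", "background_se_rate", "multi_code_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.label_noise_rate < 0.5):
            raise ValidationError("label_noise_rate must be in [0, 0.5)")
        if self.shared_bits_per_branch < 0 or self.shared_bits_per_branch > self.fingerprint_bits:
            raise ValidationError("shared_bits_per_branch outside fingerprint width")


@dataclass
class SyntheticCorpus:
    """A generated corpus: drugs, code tree, and truth tables per level."""

    drugs: list[DrugRecord]
    codes: dict[int, list[AtcCode]]
    truth: dict[int, AssociationTable]
    drug_leaves: dict[str, list[str]]
    config: SyntheticConfig

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]


def _build_leaves(branching: Sequence[int]) -> list[str]:
    leaves = []
    for i1 in range(branching[0]):
        l1 = string.ascii_uppercase[i1]
        for i2 in range(branching[1]):
            l2 = f"{l1}{i2 + 1:02d}"
            for i3 in range(branching[2]):
                l3 = l2 + string.ascii_uppercase[i3]
                for i4 in range(branching[3]):
                    leaves.append(l3 + string.ascii_uppercase[i4])
    return leaves


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    leaves = _build_leaves(config.branching)
    n_bits = config.fingerprint_bits

    # every tree node gets a bit pool; a leaf's chain carries 4 pools
    per_level = max(config.shared_bits_per_branch // 4, 0)
    node_bits: dict[str, np.ndarray] = {}
    for leaf in leaves:
        for level in (1, 2, 3, 4):
            node = parse_atc_code(leaf, level).code
            if node not in node_bits:
                node_bits[node] = rng.choice(n_bits, size=per_level, replace=False)

    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    drug_leaves: dict[str, list[str]] = {}
    for d in drug_ids:
        chosen = [leaves[rng.integers(len(leaves))]]
        if len(leaves) > 1 and rng.random() < config.multi_code_rate:
            extra = leaves[rng.integers(len(leaves))]
            if extra not in chosen:
                chosen.append(extra)
        drug_leaves[d] = chosen

    # fingerprints: ancestor pools of every assigned leaf + background
    fingerprints: dict[str, frozenset[int]] = {}
    for d in drug_ids:
        bits: set[int] = set()
        for leaf in drug_leaves[d]:
            for level in (1, 2, 3, 4):
                bits.update(int(b) for b in node_bits[parse_atc_code(leaf, level).code])
        background = np.nonzero(rng.random(n_bits) < config.background_bit_rate)[0]
        bits.update(int(b) for b in background)
        fingerprints[d] = frozenset(bits)

    # interactions: denser within the (primary-leaf) level-2 branch
    branch2 = {d: parse_atc_code(drug_leaves[d][0], 2).code for d in drug_ids}
    partners: dict[str, set[str]] = {d: set() for d in drug_ids}
    for i, a in enumerate(drug_ids):
        for b in drug_ids[i + 1:]:
            p = (config.within_branch_ddi_prob if branch2[a] == branch2[b]
                 else config.background_ddi_prob)
            if rng.random() < p:
                partners[a].add(b)
                partners[b].add(a)

    # side effects: sampled from the level-2 branch pool + background vocab
    level2_nodes = sorted({parse_atc_code(leaf, 2).code for leaf in leaves})
    branch_pools = {
        node: [f"SE_{node}_{i}" for i in range(config.branch_se_pool_size)]
        for node in level2_nodes
    }
    bg_vocab = [f"SE_BG_{i}" for i in range(config.background_se_vocab)]
    side_effects: dict[str, frozenset[str]] = {}
    for d in drug_ids:
        ses: set[str] = set()
        for leaf in drug_leaves[d]:
            pool = branch_pools[parse_atc_code(leaf, 2).code]
            ses.update(se for se in pool if rng.random() < config.se_inclusion_rate)
        ses.update(se for se in bg_vocab if rng.random() < config.background_se_rate)
        side_effects[d] = frozenset(ses)

    drugs = [
        DrugRecord(
            drug_id=d,
            fingerprint=fingerprints[d],
            ddi_partners=frozenset(partners[d]),
            side_effects=side_effects[d],
            n_bits=n_bits,
        )
        for d in drug_ids
    ]

    pairs = [(d, leaf) for d in drug_ids for leaf in drug_leaves[d]]
    codes: dict[int, list[AtcCode]] = {}
    truth: dict[int, AssociationTable] = {}
    for level in (1, 2, 3, 4):
        table = build_association_table(pairs, level, drug_ids)
        if config.label_noise_rate > 0:
            noise_rng = np.random.default_rng((config.seed * 4099 + level) % 2**31)
            rows, cols = np.nonzero(table.matrix)
            for r, c in zip(rows, cols):
                if (table.matrix[r].sum() > 1  # never orphan a drug
                        and noise_rng.random() < config.label_noise_rate):
                    table.matrix[r, c] = 0
        truth[level] = table
        codes[level] = [parse_atc_code(c, level) for c in table.code_labels]

    return SyntheticCorpus(drugs=drugs, codes=codes, truth=truth,
                           drug_leaves=drug_leaves, config=config)


def planted_signal_strength(
    corpus: SyntheticCorpus, channel: str, level: int = 2
) -> float:
    """Mean within-group minus between-group similarity for one channel.

    Two drugs are "within" one group when they share at least one true code
    at ``level``.  A value near zero means no planted signal; larger values
    mean the channel separates the classification groups more cleanly.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"channel must be one of {CHANNELS}")
    sim = build_similarity_matrix(corpus.drugs, channel).values
    member = corpus.truth[level].matrix.astype(bool)
    shares = (member @ member.T) > 0  # drugs sharing >= 1 code
    mask_offdiag = ~np.eye(len(corpus.drugs), dtype=bool)
    within = sim[shares & mask_offdiag]
    between = sim[(~shares) & mask_offdiag]
    if within.size == 0 or between.size == 0:
        return 0.0
    return float(within.mean() - between.mean())


def write_corpus(corpus: SyntheticCorpus, out_dir: "str | Path") -> dict[str, Path]:
    """Write the TSV dialects the loaders consume, plus a manifest JSON."""
    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": out / "fingerprints.tsv",
        "ddi": out / "ddi.tsv",
        "side_effects": out / "side_effects.tsv",
        "associations": out / "associations.tsv",
        "manifest": out / "manifest.json",
    }
    io_mod.write_fingerprints(corpus.drugs, paths["fingerprints"])
    io_mod.write_ddi_edges(corpus.drugs, paths["ddi"])
    io_mod.write_side_effects(corpus.drugs, paths["side_effects"])
    pairs = [(d, leaf) for d in corpus.drug_ids for leaf in corpus.drug_leaves[d]]
    io_mod.write_associations(pairs, paths["associations"])
    manifest = {"config": asdict(corpus.config),
                "n_drugs": len(corpus.drugs),
                "n_leaf_codes": len(corpus.codes[4])}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
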