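"""Drug-drug similarity channels: chemical structure, interactions, side effects.

Three views of drug relatedness, all reduced to intersection-over-union on
sets:

* ``CS`` — Tanimoto coefficient on circular-fingerprint bit sets (default
  1024-bit ECFP-style fingerprints).
* ``DDI`` — Jaccard coefficient on interaction-partner sets: two drugs that
  interact with the same third drugs are presumed functionally similar.
* ``SE`` — Jaccard coefficient on side-effect sets.

A drug with an empty feature set in a channel is assigned similarity 0 to
everything, including itself: an empty record carries no evidence, so we do
not pretend it is self-similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "CHANNELS",
    "DrugRecord",
    "SimilarityMatrix",
    "tanimoto",
    "jaccard",
    "build_similarity_matrix",
    "fingerprints_from_smiles",
]

CHANNELS = ("CS", "DDI", "SE")


@dataclass(frozen=True)
class DrugRecord:
    """A drug's three feature sets.

    ``fingerprint`` holds set-bit positions in ``0..n_bits-1``;
    ``ddi_partners`` holds ids of interacting drugs (never the drug itself);
    ``side_effects`` holds side-effect identifiers.
    """

    drug_id: str
    fingerprint: frozenset[int] = field(default_factory=frozenset)
    ddi_partners: frozenset[str] = field(default_factory=frozenset)
    side_effects: frozenset[str] = field(default_factory=frozenset)
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        object.__setattr__(self, "fingerprint", frozenset(int(b) for b in self.fingerprint))
        object.__setattr__(self, "ddi_partners", frozenset(self.ddi_partners))
        object.__setattr__(self, "side_effects", frozenset(self.side_effects))
        if self.drug_id in self.ddi_partners:
            raise ValidationError(f"drug {self.drug_id!r} listed as its own DDI partner")
        bad = [b for b in self.fingerprint if not (0 <= b < self.n_bits)]
        if bad:
            raise ValidationError(
                f"drug {self.drug_id!r}: fingerprint bits {sorted(bad)} outside 0..{self.n_bits - 1}"
            )

    def feature_set(self, channel: str) -> frozenset:
        if channel == "CS":
            return self.fingerprint
        if channel == "DDI":
            return self.ddi_partners
        if channel == "SE":
            return self.side_effects
        raise ValidationError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


def tanimoto(a: Iterable[int], b: Iterable[int]) -> float:
    """Tanimoto coefficient |a & b| / |a | b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard coefficient |a & b| / |a | b|; 0 when both sets are empty.

    Identical to :func:`tanimoto` — both are intersection-over-union — but
    kept as a separate name because the two conventions are named differently
    for fingerprints versus generic sets.
    """
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass
class SimilarityMatrix:
    """A labelled symmetric drug-drug similarity matrix for one channel."""

    channel: str
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity values shape {self.values.shape} does not match {n} labels"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def row(self, index: int) -> np.ndarray:
        return self.values[index]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def build_similarity_matrix(drugs: Sequence[DrugRecord], channel: str) -> SimilarityMatrix:
    """Pairwise channel similarity over ``drugs``, in input order.

    Vectorised as a binary incidence matrix: intersections come from one
    matrix product, unions from inclusion-exclusion.  Rows/columns of drugs
    with an empty feature set are all zero (including the diagonal).
    """
    if not drugs:
        raise ValidationError("drugs must be non-empty")
    ids = [d.drug_id for d in drugs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate drug ids: {dupes}")

    sets = [d.feature_set(channel) for d in drugs]
    vocab = sorted(set().union(*sets)) if any(sets) else []
    if not vocab:
        return SimilarityMatrix(channel, ids, np.zeros((len(ids), len(ids))))
    pos = {f: i for i, f in enumerate(vocab)}
    inc = np.zeros((len(drugs), len(vocab)), dtype=np.float64)
    for i, s in enumerate(sets):
        for f in s:
            inc[i, pos[f]] = 1.0
    inter = inc @ inc.T
    sizes = inc.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(channel, ids, values)


def fingerprints_from_smiles(
    smiles: Sequence[tuple[str, str]],
    radius: int = 2,
    n_bits: int = 1024,
    on_error: str = "report",
) -> tuple[list[DrugRecord], list[tuple[str, str]]]:
    """Circular (Morgan/ECFP-style) fingerprints from SMILES via rdkit.

    Returns ``(records, failures)`` where each record carries only ``drug_id``
    and ``fingerprint`` and failures lists ``(drug_id, smiles)`` pairs that
    could not be parsed.  With ``on_error="raise"`` the first failure raises
    instead.  Requires the optional rdkit dependency.
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - rdkit present in CI image
        raise ImportError(
            "rdkit is not installed; supply precomputed fingerprints "
            "(TSV drug_id<TAB>fingerprint) instead of SMILES"
        ) from exc

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    records: list[DrugRecord] = []
    failures: list[tuple[str, str]] = []
    for drug_id, smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            if on_error == "raise":
                raise ValidationError(f"unparseable SMILES for {drug_id!r}: {smi!r}")
            failures.append((drug_id, smi))
            continue
        bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
        records.append(DrugRecord(drug_id=drug_id, fingerprint=bits, n_bits=n_bits))
    return records, failures
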