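"""Drug-ATC association tables, negative sampling, folds, masking, label noise.

The central object is the :class:`AssociationTable`: an ``n x m_k`` binary
matrix over ``n`` drugs and the ``m_k`` distinct ATC codes at level ``k``.
From it the training set is built as all positive cells plus an equal number
of uniformly sampled zero cells (balanced negative sampling), split into
stratified cross-validation folds.

Leakage control: association features fed to the model are read from a
*masked* copy of the table in which (a) every positive cell that belongs to
the current fold's test pairs and (b) the cell of the very pair being scored
are zeroed.  The model therefore never sees the label it is asked to
predict, for either training or test pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .atc import parse_atc_code
from .errors import ValidationError

__all__ = [
    "AssociationTable",
    "LabeledPair",
    "FoldSplit",
    "build_association_table",
    "negative_sample",
    "make_folds",
    "mask_associations",
    "inject_label_noise",
]


class LabeledPair(NamedTuple):
    """A (drug index, code index) cell with its binary label."""

    drug_index: int
    code_index: int
    label: int


@dataclass
class AssociationTable:
    """Binary drugs-by-codes association matrix at one ATC level."""

    drug_labels: list[str]
    code_labels: list[str]
    matrix: np.ndarray
    level: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        n, m = len(self.drug_labels), len(self.code_labels)
        if self.matrix.shape != (n, m):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} drugs x {m} codes"
            )
        if len(set(self.drug_labels)) != n:
            raise ValidationError("duplicate drug labels")
        if len(set(self.code_labels)) != m:
            raise ValidationError("duplicate code labels")
        if self.level not in (1, 2, 3, 4):
            raise ValidationError(f"level must be in 1..4, got {self.level}")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_labels)

    @property
    def n_codes(self) -> int:
        return len(self.code_labels)

    def copy(self) -> "AssociationTable":
        return AssociationTable(
            list(self.drug_labels), list(self.code_labels), self.matrix.copy(), self.level
        )

    def positive_pairs(self) -> list[LabeledPair]:
        rows, cols = np.nonzero(self.matrix)
        return [LabeledPair(int(i), int(j), 1) for i, j in zip(rows, cols)]


@dataclass
class FoldSplit:
    """One cross-validation fold: disjoint train and test pair lists."""

    fold_id: int
    train_pairs: list[LabeledPair]
    test_pairs: list[LabeledPair]

    def __post_init__(self) -> None:
        if set(self.train_pairs) & set(self.test_pairs):
            raise ValidationError(f"fold {self.fold_id}: train and test pairs overlap")


def build_association_table(
    pairs: Sequence[tuple[str, str]],
    level: int,
    drug_universe: Sequence[str],
) -> AssociationTable:
    """Build the level-``level`` association table from (drug_id, code) pairs.

    Codes are truncated to ``level``; pairs that collapse onto the same cell
    after truncation count once.  Every drug in ``pairs`` must appear in
    ``drug_universe`` (which fixes row order); codes are ordered by first
    appearance.
    """
    drug_universe = list(drug_universe)
    if len(set(drug_universe)) != len(drug_universe):
        raise ValidationError("drug_universe contains duplicates")
    drug_pos = {d: i for i, d in enumerate(drug_universe)}
    missing = sorted({d for d, _ in pairs if d not in drug_pos})
    if missing:
        raise ValidationError(f"drugs in pairs but not in universe: {missing}")

    code_pos: dict[str, int] = {}
    cells: set[tuple[int, int]] = set()
    for drug_id, code in pairs:
        truncated = parse_atc_code(code, level).code
        if truncated not in code_pos:
            code_pos[truncated] = len(code_pos)
        cells.add((drug_pos[drug_id], code_pos[truncated]))

    matrix = np.zeros((len(drug_universe), len(code_pos)), dtype=np.int8)
    for i, j in cells:
        matrix[i, j] = 1
    return AssociationTable(drug_universe, list(code_pos), matrix, level)


def negative_sample(table: AssociationTable, seed: int) -> list[LabeledPair]:
    """All positive cells plus an equal count of distinct sampled zero cells.

    Sampling is uniform over the zero cells without replacement and fully
    determined by ``seed``.  Positives come first, in row-major cell order.
    """
    positives = table.positive_pairs()
    zero_rows, zero_cols = np.nonzero(table.matrix == 0)
    if len(zero_rows) < len(positives):
        raise ValidationError(
            f"cannot draw {len(positives)} negatives from {len(zero_rows)} zero cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zero_rows), size=len(positives), replace=False)
    negatives = [
        LabeledPair(int(zero_rows[idx]), int(zero_cols[idx]), 0) for idx in sorted(chosen)
    ]
    return positives + negatives


def make_folds(
    pairs: Sequence[LabeledPair], n_folds: int = 10, seed: int = 0
) -> list[FoldSplit]:
    """Label-stratified partition of ``pairs`` into ``n_folds`` test folds."""
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    if len(pairs) < n_folds:
        raise ValidationError(f"{len(pairs)} pairs cannot fill {n_folds} folds")
    labels = np.fromiter((p.label for p in pairs), dtype=int, count=len(pairs))
    for lbl in (0, 1):
        if 0 < (labels == lbl).sum() < n_folds:
            raise ValidationError(
                f"label {lbl} has fewer pairs than folds; stratification impossible"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
        folds.append(
            FoldSplit(
                fold_id=fold_id,
                train_pairs=[pairs[i] for i in train_idx],
                test_pairs=[pairs[i] for i in test_idx],
            )
        )
    return folds


def mask_associations(
    table: AssociationTable,
    test_pairs: Sequence[LabeledPair],
    target: LabeledPair | None = None,
) -> AssociationTable:
    """Copy of ``table`` with test-pair cells and the target cell zeroed.

    Zeroing a cell that is already 0 (every negative pair) is a no-op, so in
    effect only positive test cells and a positive target change the matrix.
    The input table is never modified.
    """
    masked = table.copy()
    n, m = masked.matrix.shape
    for p in list(test_pairs) + ([target] if target is not None else []):
        if not (0 <= p.drug_index < n and 0 <= p.code_index < m):
            raise ValidationError(f"pair {p} outside table bounds {(n, m)}")
        masked.matrix[p.drug_index, p.code_index] = 0
    return masked


def inject_label_noise(
    pairs: Sequence[LabeledPair],
    fraction: float,
    mode: str,
    table: AssociationTable,
    seed: int,
) -> list[LabeledPair]:
    """Perturb a training pair list for robustness experiments.

    ``mode="false_negative"`` relabels ``floor(fraction * P)`` randomly chosen
    positive pairs as 0 (known associations hidden in the negative set);
    ``mode="false_positive"`` appends the same count of fresh zero cells of
    ``table`` labelled 1 (unverified associations injected as positives).
    P is the number of positives in ``pairs``.  Deterministic given ``seed``.
    """
    if not (0.0 <= fraction <= 0.5):
        raise ValidationError(f"fraction must be in [0, 0.5], got {fraction}")
    if mode not in ("false_negative", "false_positive"):
        raise ValidationError(f"unknown mode {mode!r}")
    pairs = list(pairs)
    positives = [i for i, p in enumerate(pairs) if p.label == 1]
    k = int(fraction * len(positives))
    if k == 0:
        return pairs
    rng = np.random.default_rng(seed)

    if mode == "false_negative":
        flip = rng.choice(len(positives), size=k, replace=False)
        for idx in flip:
            i = positives[idx]
            pairs[i] = pairs[i]._replace(label=0)
        return pairs

    used = {(p.drug_index, p.code_index) for p in pairs}
    zero_rows, zero_cols = np.nonzero(table.matrix == 0)
    free = [
        (int(r), int(c)) for r, c in zip(zero_rows, zero_cols) if (int(r), int(c)) not in used
    ]
    if len(free) < k:
        raise ValidationError(
            f"need {k} unused zero cells for false positives, only {len(free)} available"
        )
    picked = rng.choice(len(free), size=k, replace=False)
    return pairs + [LabeledPair(free[i][0], free[i][1], 1) for i in sorted(picked)]
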