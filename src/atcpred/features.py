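"""Per-pair feature aggregation.

For a candidate pair (drug d, code a) and one drug-similarity channel, the
model input is a 2 x (n + m_k) matrix whose two rows describe the drug and
the code over the same column grid:

    row 0: [ masked association row of d over the m_k codes | drug-similarity row of d over the n drugs ]
    row 1: [ ATC-similarity row of a over the m_k codes      | masked association column of a over the n drugs ]

Columns align across rows: ATC-block column j refers to code j in both rows
and drug-block column i refers to drug i in both rows, so a 1-D convolution
sliding along the columns sees, at drug i, the aligned pair
(similarity of d to i, whether i carries a) — the evidence the
guilt-by-association assumption is built on.

The association blocks are read from a masked table (see
:func:`atcpred.dataset.mask_associations`), so the pair's own cell is always
0 in its feature and no test-fold positive is visible.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

from .dataset import AssociationTable, LabeledPair, mask_associations
from .drug_similarity import SimilarityMatrix
from .errors import ValidationError

__all__ = ["AggregatedFeature", "aggregate_features", "batch_features", "leakage_audit"]


@dataclass
class AggregatedFeature:
    """One channel's 2 x (n + m_k) input matrix for a (drug, code) pair."""

    channel: str
    drug_index: int
    code_index: int
    matrix: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


# Optional audit hook: when set (via leakage_audit), every feature assembly
# verifies that the masked table is genuinely zero at all audited cells.
_AUDIT: dict | None = None


@contextlib.contextmanager
def leakage_audit(test_pairs: Sequence[LabeledPair]) -> Iterator[dict]:
    """Instrument feature assembly to prove masked cells are never read hot.

    Within the context, every call to :func:`aggregate_features` asserts that
    the masked table it reads from is 0 at each audited (test-pair) cell and
    at the target cell, and counts the checks performed.  Yields a dict with
    ``checks`` (number of assertions made) and ``features`` (features built).
    """
    global _AUDIT
    report = {
        "cells": {(p.drug_index, p.code_index) for p in test_pairs},
        "checks": 0,
        "features": 0,
    }
    prev, _AUDIT = _AUDIT, report
    try:
        yield report
    finally:
        _AUDIT = prev


def _audit_table(table: AssociationTable, target: LabeledPair) -> None:
    if _AUDIT is None:
        return
    for i, j in _AUDIT["cells"] | {(target.drug_index, target.code_index)}:
        if table.matrix[i, j] != 0:
            raise AssertionError(
                f"leakage: cell ({i}, {j}) read unmasked during feature assembly"
            )
        _AUDIT["checks"] += 1
    _AUDIT["features"] += 1


def _check_dims(
    drug_sim: SimilarityMatrix, atc_sim: np.ndarray, table: AssociationTable
) -> tuple[int, int]:
    n, m = table.matrix.shape
    if drug_sim.values.shape != (n, n):
        raise ValidationError(
            f"drug axis mismatch: similarity is {drug_sim.values.shape}, table has {n} drugs"
        )
    atc_sim = np.asarray(atc_sim)
    if atc_sim.shape != (m, m):
        raise ValidationError(
            f"code axis mismatch: ATC similarity is {atc_sim.shape}, table has {m} codes"
        )
    return n, m


def _assemble(
    drug_index: int,
    code_index: int,
    drug_sim: SimilarityMatrix,
    atc_sim: np.ndarray,
    masked_table: AssociationTable,
) -> np.ndarray:
    n, m = masked_table.matrix.shape
    out = np.empty((2, n + m), dtype=float)
    out[0, :m] = masked_table.matrix[drug_index, :]
    out[0, m:] = drug_sim.values[drug_index, :]
    out[1, :m] = np.asarray(atc_sim)[code_index, :]
    out[1, m:] = masked_table.matrix[:, code_index]
    return out


def aggregate_features(
    drug_index: int,
    code_index: int,
    drug_sim: SimilarityMatrix,
    atc_sim: np.ndarray,
    masked_table: AssociationTable,
) -> AggregatedFeature:
    """Assemble one pair's feature matrix from pre-masked inputs.

    ``masked_table`` must already have the target pair's cell (and any
    test-fold cells) zeroed; this function is pure assembly and does not mask.
    """
    n, m = _check_dims(drug_sim, atc_sim, masked_table)
    if not (0 <= drug_index < n and 0 <= code_index < m):
        raise ValidationError(f"target ({drug_index}, {code_index}) outside {(n, m)}")
    _audit_table(masked_table, LabeledPair(drug_index, code_index, 0))
    return AggregatedFeature(
        channel=drug_sim.channel,
        drug_index=drug_index,
        code_index=code_index,
        matrix=_assemble(drug_index, code_index, drug_sim, atc_sim, masked_table),
    )


def batch_features(
    pairs: Sequence[LabeledPair],
    drug_sim: SimilarityMatrix,
    atc_sim: np.ndarray,
    table: AssociationTable,
    test_pairs: Sequence[LabeledPair] = (),
) -> list[AggregatedFeature]:
    """Features for many pairs, with fold and per-target masking applied.

    The fold mask (zeroing all ``test_pairs`` cells) is applied once; each
    pair then gets its own target cell zeroed on top, exactly as if
    ``mask_associations(table, test_pairs, pair)`` had been called per pair.
    Output order matches input order.
    """
    if not pairs:
        return []
    fold_masked = mask_associations(table, test_pairs)
    _check_dims(drug_sim, atc_sim, fold_masked)
    out = []
    for p in pairs:
        target_masked = mask_associations(fold_masked, (), p)
        out.append(
            aggregate_features(p.drug_index, p.code_index, drug_sim, atc_sim, target_masked)
        )
    return out


def feature_array(features: Sequence[AggregatedFeature]) -> np.ndarray:
    """Stack features into a (batch, 2, n + m_k) array for the model."""
    return np.stack([f.matrix for f in features], axis=0)


def export_pair_features(features: Sequence[AggregatedFeature], out_dir) -> list:
    """Debug export: one CSV per channel for a single pair's feature matrices."""
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in features:
        path = out / f"feature_{f.channel.lower()}_d{f.drug_index}_c{f.code_index}.csv"
        pd.DataFrame(f.matrix, index=["drug_row", "code_row"]).to_csv(path)
        paths.append(path)
    return paths
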