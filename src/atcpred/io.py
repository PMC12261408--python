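"""Delimited-text readers and writers for the package's external formats.

All files are headered TSV:

* fingerprints: ``drug_id<TAB>fingerprint`` where the fingerprint field is
  either a comma-separated list of set-bit positions (``3,17,940``) or a
  fixed-width hex string of exactly ``n_bits / 4`` characters encoding the
  bit vector as one big integer (bit ``i`` set iff ``int(field, 16) >> i & 1``).
  The dialect is sniffed per file: a field of exactly ``n_bits / 4`` hex
  characters is read as hex, anything else as positions.
* DDI edges: ``drug_id_a<TAB>drug_id_b``, undirected; duplicate and reversed
  duplicate edges collapse, self-edges are rejected.
* side effects: ``drug_id<TAB>side_effect_id``.
* associations: ``drug_id<TAB>atc_code``.

Similarity matrices are written as CSV with a header row and row labels in
the first column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .drug_similarity import DrugRecord, SimilarityMatrix
from .errors import ValidationError

__all__ = [
    "read_fingerprints",
    "read_ddi_edges",
    "read_side_effects",
    "read_associations",
    "load_drug_records",
    "write_fingerprints",
    "write_ddi_edges",
    "write_side_effects",
    "write_associations",
    "write_similarity_csv",
    "read_similarity_csv",
]

_HEX_CHARS = set("0123456789abcdefABCDEF")


def _read_tsv(path, columns: int, name: str) -> list[list[str]]:
    rows = []
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValidationError(f"{name} file {path} is empty")
    for lineno, line in enumerate(text[1:], start=2):  # skip header
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != columns:
            raise ValidationError(
                f"{name} file {path} line {lineno}: expected {columns} "
                f"tab-separated fields, got {len(parts)}"
            )
        rows.append(parts)
    return rows


def _parse_fingerprint(fieldvalue: str, n_bits: int, where: str) -> frozenset[int]:
    fieldvalue = fieldvalue.strip()
    if not fieldvalue:
        return frozenset()
    if len(fieldvalue) == n_bits // 4 and set(fieldvalue) <= _HEX_CHARS:
        value = int(fieldvalue, 16)
        return frozenset(i for i in range(n_bits) if (value >> i) & 1)
    try:
        bits = frozenset(int(tok) for tok in fieldvalue.split(","))
    except ValueError:
        raise ValidationError(f"{where}: unparseable fingerprint field {fieldvalue!r}") from None
    bad = [b for b in bits if not (0 <= b < n_bits)]
    if bad:
        raise ValidationError(f"{where}: bit positions {sorted(bad)} outside 0..{n_bits - 1}")
    return bits


def read_fingerprints(path, n_bits: int = 1024) -> dict[str, frozenset[int]]:
    out: dict[str, frozenset[int]] = {}
    for drug_id, fp in _read_tsv(path, 2, "fingerprint"):
        if drug_id in out:
            raise ValidationError(f"duplicate drug id {drug_id!r} in {path}")
        out[drug_id] = _parse_fingerprint(fp, n_bits, f"{path}:{drug_id}")
    return out


def read_ddi_edges(path) -> set[tuple[str, str]]:
    """Undirected edge set with canonically ordered endpoints."""
    edges: set[tuple[str, str]] = set()
    for a, b in _read_tsv(path, 2, "DDI"):
        if a == b:
            raise ValidationError(f"self-interaction {a!r} in {path}")
        edges.add((min(a, b), max(a, b)))
    return edges


def read_side_effects(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for drug_id, se in _read_tsv(path, 2, "side-effect"):
        out.setdefault(drug_id, set()).add(se)
    return out


def read_associations(path) -> list[tuple[str, str]]:
    return [(d, c) for d, c in _read_tsv(path, 2, "association")]


def load_drug_records(
    fingerprint_path=None,
    ddi_path=None,
    side_effect_path=None,
    drug_universe: Sequence[str] | None = None,
    n_bits: int = 1024,
) -> list[DrugRecord]:
    """Assemble DrugRecords from whichever feature files are given.

    The drug universe defaults to the union of ids seen in the files, in
    sorted order; drugs absent from a file get an empty set for that channel.
    """
    fingerprints = read_fingerprints(fingerprint_path, n_bits) if fingerprint_path else {}
    edges = read_ddi_edges(ddi_path) if ddi_path else set()
    side_effects = read_side_effects(side_effect_path) if side_effect_path else {}

    partners: dict[str, set[str]] = {}
    for a, b in edges:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    if drug_universe is None:
        drug_universe = sorted(set(fingerprints) | set(partners) | set(side_effects))
    if not drug_universe:
        raise ValidationError("no drugs found in any input file")
    return [
        DrugRecord(
            drug_id=d,
            fingerprint=fingerprints.get(d, frozenset()),
            ddi_partners=frozenset(partners.get(d, set())) - {d},
            side_effects=frozenset(side_effects.get(d, set())),
            n_bits=n_bits,
        )
        for d in drug_universe
    ]


# -- writers -------------------------------------------------------------------

def write_fingerprints(drugs: Iterable[DrugRecord], path) -> None:
    lines = ["drug_id\tfingerprint"]
    for d in drugs:
        lines.append(f"{d.drug_id}\t{','.join(str(b) for b in sorted(d.fingerprint))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ddi_edges(drugs: Iterable[DrugRecord], path) -> None:
    edges = set()
    for d in drugs:
        for p in d.ddi_partners:
            edges.add((min(d.drug_id, p), max(d.drug_id, p)))
    lines = ["drug_id_a\tdrug_id_b"]
    lines += [f"{a}\t{b}" for a, b in sorted(edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_side_effects(drugs: Iterable[DrugRecord], path) -> None:
    lines = ["drug_id\tside_effect_id"]
    for d in drugs:
        lines += [f"{d.drug_id}\t{se}" for se in sorted(d.side_effects)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_associations(pairs: Iterable[tuple[str, str]], path) -> None:
    lines = ["drug_id\tatc_code"]
    lines += [f"{d}\t{c}" for d, c in pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def write_similarity_csv(matrix: "SimilarityMatrix | pd.DataFrame", path) -> None:
    df = matrix.to_dataframe() if isinstance(matrix, SimilarityMatrix) else matrix
    df.to_csv(path, index=True)


def read_similarity_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
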