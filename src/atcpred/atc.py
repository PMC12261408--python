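"""ATC code parsing and hierarchical code-code similarity measures.

The Anatomical Therapeutic Chemical (ATC) system classifies a drug with a
5-level code; this package works with levels 1-4 (level 5 enumerates
individual substances and carries no class structure).  A level-4 code such
as ``A03AA`` decomposes into the nested prefix chain

    A  <  A03  <  A03A  <  A03AA

(1, 3, 4 and 5 characters for levels 1-4).  All three similarity measures
implemented here are functions of the shared-prefix depth
``N_k(a, b) = |S_k(a) & S_k(b)|``, where ``S_k`` is the set of a code's
prefixes down to level ``k``; because prefixes nest, ``N_k`` is simply the
number of leading levels on which the two codes agree.

Measures
--------
``whs``
    Weighted-hierarchical similarity.  Each agreeing level ``i`` (counted
    from 0) contributes a quadratic weight ``(k - i)**2``, so disagreement
    near the root costs far more than disagreement at the leaves, and a
    smoothing term ``k**2`` keeps the value positive:

        WHS_k(a, b) = (2*W_k^{N_k(a,b)} + k^2) / (2*W_k^k + k^2),
        W_k^n = sum_{i=0}^{n-1} (k - i)^2.

``rnp_sim``
    The unweighted counterpart, (2*N_k + 1) / (2k + 1): every level counts
    the same.  At k = 1 it coincides with WHS exactly.

``np_sim``
    A node-weighted exponential-decay similarity,
    w(a) * w(b) * exp(-0.25 * d(a, b)), where w is the inverse frequency of
    the code among positive samples and d is the tree distance
    2 * (k - N_k) (edges up to the deepest common ancestor and back down).
    Unlike the other two it is not bounded by 1: rare codes get large
    weights by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LookupMissingError, ValidationError

__all__ = [
    "ATC_LEVEL_LENGTHS",
    "AtcCode",
    "NpSimParams",
    "parse_atc_code",
    "shared_levels",
    "level_weight",
    "whs",
    "rnp_sim",
    "np_sim",
    "atc_similarity_matrix",
]

#: Character length of an ATC code truncated to each level.
ATC_LEVEL_LENGTHS: dict[int, int] = {1: 1, 2: 3, 3: 4, 4: 5}

# (start, end, predicate, description) for each level's new characters
_LEVEL_CHAR_RULES = [
    (0, 1, str.isalpha, "an uppercase letter"),
    (1, 3, str.isdigit, "a digit"),
    (3, 4, str.isalpha, "an uppercase letter"),
    (4, 5, str.isalpha, "an uppercase letter"),
]


@dataclass(frozen=True)
class AtcCode:
    """An ATC code truncated to ``level``, with its nested prefix chain.

    ``prefixes[j]`` is the code truncated to level ``j+1``; the full set of
    prefixes is the S_k of the similarity formulas.
    """

    code: str
    level: int
    prefixes: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_atc_code(code: str, level: int) -> AtcCode:
    """Parse ``code`` at ``level`` (1-4), truncating deeper input.

    Raises :class:`ValidationError` naming the offending position if any
    character violates the letter/digit/letter/letter ATC layout, if the
    code is too short for the requested level, or if ``level`` is out of
    range.
    """
    if not isinstance(code, str) or not code:
        raise ValidationError("ATC code must be a non-empty string")
    if level not in ATC_LEVEL_LENGTHS:
        raise ValidationError(f"ATC level must be in 1..4, got {level!r}")
    code = code.strip().upper()
    need = ATC_LEVEL_LENGTHS[level]
    if len(code) < need:
        raise ValidationError(
            f"code {code!r} has {len(code)} characters but level {level} "
            f"requires at least {need}"
        )
    truncated = code[:need]
    for lvl_idx, (start, end, pred, desc) in enumerate(_LEVEL_CHAR_RULES):
        if start >= need:
            break
        for pos in range(start, min(end, need)):
            ch = truncated[pos]
            if not (pred(ch) and (ch.isdigit() or ch.isupper())):
                raise ValidationError(
                    f"code {code!r}: position {pos} must be {desc}, got {ch!r}"
                )
        del lvl_idx
    prefixes = tuple(truncated[: ATC_LEVEL_LENGTHS[lv]] for lv in range(1, level + 1))
    return AtcCode(code=truncated, level=level, prefixes=prefixes)


def _as_code(a: "AtcCode | str", k: int) -> AtcCode:
    if isinstance(a, AtcCode):
        if a.level < k:
            raise ValidationError(
                f"code {a.code!r} parsed at level {a.level} cannot be compared at level {k}"
            )
        return a
    return parse_atc_code(a, k)


def shared_levels(a: "AtcCode | str", b: "AtcCode | str", k: int) -> int:
    """Size of the intersection of the two level-k prefix sets.

    Prefix sets nest, so this equals the number of leading levels (0..k) on
    which the codes agree.
    """
    if k not in ATC_LEVEL_LENGTHS:
        raise ValidationError(f"level k must be in 1..4, got {k!r}")
    a, b = _as_code(a, k), _as_code(b, k)
    n = 0
    for lv in range(k):
        if a.prefixes[lv] == b.prefixes[lv]:
            n += 1
        else:
            break
    return n


def level_weight(k: int, n: int) -> int:
    """Cumulative hierarchy weight W_k^n = sum_{i=0}^{n-1} (k - i)^2.

    Zero at n = 0; each further shared level adds (k - n)^2, so increments
    shrink as agreement deepens.
    """
    if k not in ATC_LEVEL_LENGTHS:
        raise ValidationError(f"level k must be in 1..4, got {k!r}")
    if not (0 <= n <= k):
        raise ValidationError(f"n must satisfy 0 <= n <= k={k}, got {n}")
    return sum((k - i) ** 2 for i in range(n))


def whs(a: "AtcCode | str", b: "AtcCode | str", k: int) -> float:
    """Weighted-hierarchical similarity in (0, 1]; 1 iff the codes agree through level k."""
    n = shared_levels(a, b, k)
    return (2 * level_weight(k, n) + k * k) / (2 * level_weight(k, k) + k * k)


def rnp_sim(a: "AtcCode | str", b: "AtcCode | str", k: int) -> float:
    """Uniform-weight prefix similarity (2*N_k + 1) / (2k + 1)."""
    n = shared_levels(a, b, k)
    return (2 * n + 1) / (2 * k + 1)


@dataclass
class NpSimParams:
    """Code weights for :func:`np_sim`.

    ``code_frequency`` maps each code (string at the working level) to its
    proportion of the positive samples at that level, in (0, 1]; the weight
    w(a) = 1 / frequency is then >= 1.  ``distance_scale`` is the decay rate
    of the exponential term (0.25 in the reference formulation).
    """

    code_frequency: Mapping[str, float]
    distance_scale: float = 0.25

    def __post_init__(self) -> None:
        for code, f in self.code_frequency.items():
            if not (0.0 < f <= 1.0):
                raise ValidationError(
                    f"frequency for {code!r} must lie in (0, 1], got {f}"
                )

    @classmethod
    def from_pairs(cls, codes: Iterable[str], level: int) -> "NpSimParams":
        """Estimate frequencies from the code column of a positive-pair list.

        Each code is truncated to ``level`` first; the frequency of a code is
        its share of the truncated list.  Compute this from training pairs
        only: using test pairs would leak label information into the kernel.
        """
        truncated = [parse_atc_code(c, level).code for c in codes]
        if not truncated:
            raise ValidationError("cannot estimate code frequencies from an empty list")
        total = len(truncated)
        counts: dict[str, int] = {}
        for c in truncated:
            counts[c] = counts.get(c, 0) + 1
        return cls(code_frequency={c: n / total for c, n in counts.items()})

    def weight(self, code: str) -> float:
        try:
            return 1.0 / self.code_frequency[code]
        except KeyError:
            raise LookupMissingError(
                f"code {code!r} has no recorded positive-sample frequency"
            ) from None


def np_sim(a: "AtcCode | str", b: "AtcCode | str", params: NpSimParams, k: int) -> float:
    """Inverse-frequency-weighted exponential-decay similarity (unbounded above).

    Tree distance d(a, b) = 2 * (k - N_k(a, b)): the number of edges on the
    path through the deepest common ancestor when both codes sit at depth k.
    """
    a, b = _as_code(a, k), _as_code(b, k)
    n = shared_levels(a, b, k)
    d = 2 * (k - n)
    return params.weight(a.code) * params.weight(b.code) * math.exp(-params.distance_scale * d)


_MEASURES = ("whs", "rnpsim", "npsim")


def atc_similarity_matrix(
    codes: Sequence["AtcCode | str"],
    measure: str,
    k: int,
    params: NpSimParams | None = None,
) -> pd.DataFrame:
    """Symmetric code-code similarity matrix, labelled by truncated codes.

    ``measure`` is one of ``"whs"``, ``"rnpsim"``, ``"npsim"`` (NPSim needs
    ``params``).  Codes are truncated to level ``k``; duplicates created by
    the truncation are collapsed to a single row/column, while codes that
    were already duplicated in the input are rejected.
    """
    if not codes:
        raise ValidationError("codes must be non-empty")
    measure = measure.lower().replace("_", "")
    if measure not in _MEASURES:
        raise ValidationError(f"measure must be one of {_MEASURES}, got {measure!r}")
    if measure == "npsim" and params is None:
        raise ValidationError("npsim requires NpSimParams")

    raw = [c.code if isinstance(c, AtcCode) else str(c).strip().upper() for c in codes]
    if len(set(raw)) != len(raw):
        dupes = sorted({c for c in raw if raw.count(c) > 1})
        raise ValidationError(f"duplicate code labels in input: {dupes}")

    parsed: list[AtcCode] = []
    seen: set[str] = set()
    for c in codes:
        pc = _as_code(c, k) if isinstance(c, AtcCode) else parse_atc_code(c, k)
        pc = parse_atc_code(pc.code, k)
        if pc.code not in seen:  # collapse truncation-induced duplicates
            seen.add(pc.code)
            parsed.append(pc)

    m = len(parsed)
    values = np.empty((m, m), dtype=float)
    for i, j in itertools.combinations_with_replacement(range(m), 2):
        if measure == "whs":
            v = whs(parsed[i], parsed[j], k)
        elif measure == "rnpsim":
            v = rnp_sim(parsed[i], parsed[j], k)
        else:
            v = np_sim(parsed[i], parsed[j], params, k)
        values[i, j] = values[j, i] = v
    labels = [c.code for c in parsed]
    return pd.DataFrame(values, index=labels, columns=labels)
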