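"""Prediction accuracy: sensitivity / PPV / F-measure and class averages.

A predicted base pair counts as correct only on an exact index match
(no one-position slippage).  Corner conventions, chosen because the
measures are undefined there: two empty structures compare as (1, 1, 1);
if exactly one side is empty the undefined ratio is set to 0 and F is 0.

Three schemes average a per-record measure over ``n`` RNA classes
``C_1..C_n`` with sizes ``l_1..l_n`` and mean normalized within-class
structure similarities ``s_1..s_n``:

* unweighted — mean of the class means (each class counts equally);
* weighted — mean over the pooled records (each sequence counts equally);
* S-weighted — class means combined with weights ``l_i^(1 - s_i)``, so a
  class of highly similar sequences is discounted toward counting once.
  With all ``s_i = 0`` this is the weighted average, with all ``s_i = 1``
  the unweighted one.

The normalized similarity between two (sequence, structure) records is a
documented stand-in: the records are aligned through a banded edit
alignment (via edlib) over a combined alphabet of (residue, pairing
state) symbols — 4 bases x {paired-open, paired-close, unpaired} — and
the score blends the matched-pair F-measure with sequence identity
(matching aligned columns over the mean of the two lengths), 50/50.  It
is symmetric, 1.0 for identical records, and always in [0, 1].  A
per-class similarity computed by any external procedure can be supplied
instead wherever ``s_i`` is consumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import edlib
import numpy as np

from .structure_io import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "AccuracyTriple",
    "ClassAccuracy",
    "compare",
    "f_measure",
    "unweighted_average",
    "weighted_average",
    "s_weighted_average",
    "normalized_similarity",
    "class_similarity",
]


@dataclass(frozen=True)
class AccuracyTriple:
    sensitivity: float
    ppv: float
    f: float

    def __iter__(self):
        return iter((self.sensitivity, self.ppv, self.f))


@dataclass(frozen=True)
class ClassAccuracy:
    """Per-class bookkeeping: label, size, similarity and per-record values."""

    label: str
    similarity: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not self.values:
            raise ValueError(f"class {self.label!r} has no records")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"class {self.label!r}: similarity must be in [0, 1]")

    @property
    def size(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def f_measure(sensitivity: float, ppv: float) -> float:
    if sensitivity + ppv == 0:
        return 0.0
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def compare(reference: SecondaryStructure, predicted: SecondaryStructure) -> AccuracyTriple:
    """Sensitivity, PPV and F-measure of a prediction against a reference."""
    if reference.length != predicted.length:
        raise StructureError(
            f"cannot compare structures of lengths {reference.length} and {predicted.length}"
        )
    n_ref, n_pred = len(reference.pairs), len(predicted.pairs)
    if n_ref == 0 and n_pred == 0:
        return AccuracyTriple(1.0, 1.0, 1.0)
    tp = len(reference.pairs & predicted.pairs)
    sens = tp / n_ref if n_ref else 0.0
    ppv = tp / n_pred if n_pred else 0.0
    return AccuracyTriple(sens, ppv, f_measure(sens, ppv))


# ---------------------------------------------------------------------------
# class averages


def unweighted_average(classes: Sequence[ClassAccuracy]) -> float:
    """Mean of the class means: every class counts equally."""
    if not classes:
        raise ValueError("need at least one class")
    return float(np.mean([c.mean for c in classes]))


def weighted_average(classes: Sequence[ClassAccuracy]) -> float:
    """Pooled mean: every record counts equally, regardless of class."""
    if not classes:
        raise ValueError("need at least one class")
    total = sum(sum(c.values) for c in classes)
    count = sum(c.size for c in classes)
    return float(total / count)


def s_weighted_average(classes: Sequence[ClassAccuracy]) -> float:
    """Similarity-discounted average with class weights ``l_i^(1 - s_i)``."""
    if not classes:
        raise ValueError("need at least one class")
    weights = np.array([c.size ** (1.0 - c.similarity) for c in classes])
    means = np.array([c.mean for c in classes])
    return float((weights * means).sum() / weights.sum())


# ---------------------------------------------------------------------------
# normalized structure similarity (SimTree stand-in)


_STATE = {"(": 0, ")": 1, ".": 2}
_BASE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 0}
_SYMBOLS = "abcdefghijkl"


def _combined_symbols(seq: RnaSequence, struct: SecondaryStructure) -> str:
    """One symbol per position encoding (residue, pairing state)."""
    db = struct.to_dot_bracket()
    return "".join(
        _SYMBOLS[_BASE[r] * 3 + _STATE[s]] for r, s in zip(seq.residues, db)
    )


def _aligned_columns(a: str, b: str) -> list[tuple[int, int]]:
    """Columns (i in a, j in b) matched by a banded edit alignment of a and b."""
    res = edlib.align(a, b, task="path")
    cols = []
    i = j = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        count = int(count)
        if op in "=XM":
            cols.extend((i + k, j + k) for k in range(count))
            i += count
            j += count
        elif op == "D":  # consumes the target (b)
            j += count
        else:  # "I" consumes the query (a)
            i += count
    return cols


def normalized_similarity(
    seq_a: RnaSequence,
    struct_a: SecondaryStructure,
    seq_b: RnaSequence,
    struct_b: SecondaryStructure,
) -> float:
    """Similarity of two (sequence, structure) records, in [0, 1].

    See the module docstring for the definition.  Symmetric by construction
    (inputs are ordered canonically before alignment).
    """
    key_a = (seq_a.length, seq_a.residues, struct_a.to_dot_bracket())
    key_b = (seq_b.length, seq_b.residues, struct_b.to_dot_bracket())
    if key_b < key_a:
        seq_a, struct_a, seq_b, struct_b = seq_b, struct_b, seq_a, struct_a
    cols = _aligned_columns(
        _combined_symbols(seq_a, struct_a), _combined_symbols(seq_b, struct_b)
    )
    a_to_b = dict(cols)
    pairs_b = struct_b.pairs
    matched = sum(
        1
        for i, j in struct_a.pairs
        if (a_to_b.get(i), a_to_b.get(j)) in pairs_b
    )
    na, nb = len(struct_a.pairs), len(struct_b.pairs)
    if na == 0 and nb == 0:
        pair_f = 1.0
    elif na == 0 or nb == 0:
        pair_f = 0.0
    else:
        pair_f = f_measure(matched / na, matched / nb)
    if cols:
        identity = sum(
            1 for i, j in cols if seq_a.residues[i] == seq_b.residues[j]
        ) / (0.5 * (seq_a.length + seq_b.length))
    else:
        identity = 0.0
    return 0.5 * pair_f + 0.5 * identity


def class_similarity(
    records,
    similarity: Callable[..., float] = normalized_similarity,
) -> float:
    """Mean pairwise similarity of a class's reference structures.

    ``records`` is a sequence of objects with ``sequence`` and ``reference``
    attributes (e.g. :class:`foldeval.structure_io.ReferenceRecord`).  A
    single-record class has similarity 1.0 by convention.
    """
    records = list(records)
    if not records:
        raise ValueError("empty class")
    if len(records) == 1:
        return 1.0
    vals = [
        similarity(a.sequence, a.reference, b.sequence, b.reference)
        for a, b in combinations(records, 2)
    ]
    return float(np.mean(vals))
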