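"""Reading, validating and writing RNA sequences, secondary structures
and class-labelled benchmark datasets.

Formats
-------
* dot-bracket strings over ``.()`` (pseudoknot alphabets are rejected, or
  optionally stripped with ``drop_pseudoknots=True``);
* CT connect files (Zuker dialect: ``<n> <title>`` header, six columns,
  1-based indices, 0 marks an unpaired base);
* FASTA-with-structure: per record a ``>`` header (with an optional
  ``class=<label>`` token), one sequence line, one dot-bracket line;
* a tab-separated ``record_id<TAB>class_label`` manifest.

Internally everything is 0-based; files keep their native conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "StructureError",
    "FormatError",
    "RnaSequence",
    "SecondaryStructure",
    "ReferenceRecord",
    "BenchmarkDataset",
    "MIN_HAIRPIN",
    "parse_dot_bracket",
    "parse_ct",
    "write_ct",
    "read_dataset",
    "write_dataset",
    "parse_manifest",
]

#: minimum number of unpaired bases enclosed by a pair (standard convention)
MIN_HAIRPIN = 3

RNA_ALPHABET = frozenset("ACGUN")

PSEUDOKNOT_OPEN = "[{<ABCDEFGHIJKLMNOPQRSTUVWXYZ"
PSEUDOKNOT_CLOSE = "]}>abcdefghijklmnopqrstuvwxyz"


class StructureError(ValueError):
    """A secondary structure violates a structural invariant."""


class FormatError(ValueError):
    """A file or string does not conform to its declared format."""


def _normalize_residues(residues: str) -> str:
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with an identifier and an optional class label.

    Residues are normalised on construction: lowercase is raised to upper
    case and T becomes U. ``N`` is tolerated but never pairs.
    """

    id: str
    residues: str
    class_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize_residues(self.residues))
        if not self.residues:
            raise StructureError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise StructureError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of given length.

    Pairs are 0-based ``(i, j)`` with ``i < j``.  Invariants checked on every
    construction: indices in range, each index in at most one pair, no two
    pairs cross, and every hairpin loop has at least ``MIN_HAIRPIN`` unpaired
    bases (``j - i >= MIN_HAIRPIN + 1``).
    """

    length: int
    pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        )
        if self.length < 1:
            raise StructureError("structure length must be positive")
        seen: set[int] = set()
        for i, j in self.pairs:
            if i < 0 or j >= self.length:
                raise StructureError(f"pair ({i},{j}) out of range for length {self.length}")
            if j - i < MIN_HAIRPIN + 1:
                raise StructureError(
                    f"pair ({i},{j}) closes a hairpin loop of {j - i - 1} < {MIN_HAIRPIN} bases"
                )
            if i in seen or j in seen:
                raise StructureError(f"index in pair ({i},{j}) participates in two pairs")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if k >= j:
                    break
                if l > j:  # i < k < j < l
                    raise StructureError(
                        f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)"
                    )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        """Map each paired index to its partner."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass
class ReferenceRecord:
    """A sequence together with its reference structure and any predictions."""

    sequence: RnaSequence
    reference: SecondaryStructure
    predictions: dict[str, SecondaryStructure] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference.length != self.sequence.length:
            raise StructureError(
                f"record {self.sequence.id!r}: reference structure length "
                f"{self.reference.length} != sequence length {self.sequence.length}"
            )


@dataclass
class BenchmarkDataset:
    """An ordered collection of records grouped into named RNA classes."""

    name: str
    records: list[ReferenceRecord]

    @property
    def classes(self) -> dict[str, list[int]]:
        """Mapping class label -> record indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for idx, rec in enumerate(self.records):
            label = rec.sequence.class_label
            if label is None:
                raise FormatError(f"record {rec.sequence.id!r} has no class label")
            out.setdefault(label, []).append(idx)
        return out

    def class_records(self, label: str) -> list[ReferenceRecord]:
        return [self.records[i] for i in self.classes[label]]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# dot-bracket


def parse_dot_bracket(text: str, drop_pseudoknots: bool = False) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Only ``.()`` are accepted.  Pseudoknot bracket alphabets (``[ ] { }``,
    letters, ...) are rejected with a :class:`FormatError` unless
    ``drop_pseudoknots`` is set, in which case those positions are read as
    unpaired.
    """
    text = text.strip()
    if not text:
        raise FormatError("empty dot-bracket string")
    pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch == ".":
            continue
        elif drop_pseudoknots and (ch in PSEUDOKNOT_OPEN or ch in PSEUDOKNOT_CLOSE):
            continue
        else:
            raise FormatError(
                f"unsupported character {ch!r} at position {pos} "
                "(pseudoknot alphabets are not accepted; see drop_pseudoknots)"
            )
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    try:
        return SecondaryStructure(length=len(text), pairs=frozenset(pairs))
    except StructureError as exc:
        raise StructureError(f"invalid dot-bracket structure: {exc}") from exc


# ---------------------------------------------------------------------------
# CT connect format


def parse_ct(text: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Parse a single CT connect-format record (1-based, 0 = unpaired)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT record")
    head = lines[0].split(None, 1)
    try:
        n = int(head[0])
    except ValueError as exc:
        raise FormatError(f"CT header does not start with a count: {lines[0]!r}") from exc
    title = head[1].strip() if len(head) > 1 else "ct_record"
    body = lines[1:]
    if len(body) != n:
        raise FormatError(f"CT header declares {n} bases but {len(body)} lines follow")
    residues = []
    partner = [0] * (n + 1)  # 1-based
    for lineno, line in enumerate(body, start=2):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"CT line {lineno}: expected 6 columns, got {len(cols)}")
        idx, base, pair_col = int(cols[0]), cols[1], int(cols[4])
        if idx != lineno - 1:
            raise FormatError(f"CT line {lineno}: index {idx} out of order")
        if pair_col < 0 or pair_col > n:
            raise FormatError(f"CT line {lineno}: pairing index {pair_col} out of range")
        residues.append(base)
        partner[idx] = pair_col
    for i in range(1, n + 1):
        j = partner[i]
        if j and partner[j] != i:
            raise FormatError(
                f"CT asymmetric pairing: line {i + 1} pairs to {j} "
                f"but line {j + 1} pairs to {partner[j]}"
            )
    pairs = frozenset((i - 1, partner[i] - 1) for i in range(1, n + 1) if partner[i] > i)
    seq = RnaSequence(id=title, residues="".join(residues))
    try:
        struct = SecondaryStructure(length=n, pairs=pairs)
    except StructureError as exc:
        raise StructureError(f"invalid CT structure {title!r}: {exc}") from exc
    return seq, struct


def write_ct(sequence: RnaSequence, structure: SecondaryStructure) -> str:
    """Render a (sequence, structure) as a CT connect record."""
    if structure.length != sequence.length:
        raise StructureError("sequence/structure length mismatch")
    partner = structure.partner_map()
    n = sequence.length
    lines = [f"{n} {sequence.id}"]
    for i in range(n):
        j = partner.get(i, -1) + 1
        lines.append(f"{i + 1} {sequence.residues[i]} {i} {i + 2 if i + 1 < n else 0} {j} {i + 1}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA-with-structure datasets


def parse_manifest(text: str) -> dict[str, str]:
    """Parse a ``record_id<TAB>class_label`` manifest."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise FormatError(f"manifest line {lineno}: expected 2 tab-separated columns")
        out[cols[0]] = cols[1]
    return out


def _parse_header(line: str) -> tuple[str, str | None]:
    if not line.startswith(">"):
        raise FormatError(f"expected '>' header, got {line!r}")
    tokens = line[1:].split()
    if not tokens:
        raise FormatError("empty FASTA header")
    rec_id = tokens[0]
    label = None
    for tok in tokens[1:]:
        if tok.startswith("class="):
            label = tok[len("class=") :]
    return rec_id, label


def read_dataset(
    path,
    manifest_path=None,
    name: str | None = None,
    drop_pseudoknots: bool = False,
) -> BenchmarkDataset:
    """Read a FASTA-with-structure file into a :class:`BenchmarkDataset`.

    Class labels come from the manifest when given, otherwise from the
    ``class=<label>`` header token.  Records keep file order.
    """
    from pathlib import Path

    path = Path(path)
    manifest = parse_manifest(Path(manifest_path).read_text()) if manifest_path else {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError(
            f"{path.name}: expected records of 3 lines (header, sequence, structure)"
        )
    records: list[ReferenceRecord] = []
    for k in range(0, len(lines), 3):
        rec_id, label = _parse_header(lines[k])
        if rec_id in manifest:
            label = manifest[rec_id]
        if label is None:
            raise FormatError(f"record {rec_id!r}: no class label in header or manifest")
        seq_line, db_line = lines[k + 1], lines[k + 2]
        if len(seq_line) != len(db_line):
            raise FormatError(
                f"record {rec_id!r}: structure length {len(db_line)} != "
                f"sequence length {len(seq_line)}"
            )
        seq = RnaSequence(id=rec_id, residues=seq_line, class_label=label)
        struct = parse_dot_bracket(db_line, drop_pseudoknots=drop_pseudoknots)
        records.append(ReferenceRecord(sequence=seq, reference=struct))
    ds = BenchmarkDataset(name=name or path.stem, records=records)
    ds.classes  # validate labels
    return ds


def write_dataset(dataset: BenchmarkDataset, path) -> None:
    """Write a dataset as FASTA-with-structure (labels in the headers)."""
    from pathlib import Path

    chunks = []
    for rec in dataset.records:
        label = rec.sequence.class_label
        header = f">{rec.sequence.id}" + (f" class={label}" if label else "")
        chunks.append(f"{header}\n{rec.sequence.residues}\n{rec.reference.to_dot_bracket()}\n")
    Path(path).write_text("".join(chunks))
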