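"""A reduced additive nearest-neighbor free-energy model.

The model scores a pseudoknot-free secondary structure as the sum of
independent loop terms: stacked pairs (a 6x6 table over the allowed pairs
AU/UA/CG/GC/GU/UG), length-dependent hairpin/bulge/internal-loop penalties
(tabulated for loop sizes 0..30 with logarithmic extrapolation beyond), an
affine multiloop cost ``a + b*(branches incl. closing pair) + c*unpaired``,
and a terminal AU/GU penalty.  The exterior loop costs nothing, so the open
chain always has energy exactly 0.

The terminal penalty is booked per loop: an AU/UA/GU/UG pair pays
``terminal_au`` once for every adjacent loop that is not a stack.  A pair in
the middle of a helix therefore pays nothing, while each helix-end pair pays
once per exposed side.  This convention keeps the energy exactly additive
over the loop decomposition, which the folding recursions rely on.

This is deliberately a small model (~100 parameters): no dangles, coaxial
stacking, sequence-dependent loop terms or special hairpins.  The packaged
``toy37`` and ``toy37_alt`` parameter files are illustrative fixtures, not
measured thermodynamic values; ``toy37_alt`` is a perturbed variant so that
comparisons across parameter sets can be exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .structure_io import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "ALLOWED_PAIRS",
    "WEAK_PAIRS",
    "ParameterError",
    "IncompatibleStructureError",
    "NNParameterSet",
    "Loop",
    "load_parameters",
    "write_parameters",
    "load_default",
    "loop_decomposition",
    "free_energy",
]

ALLOWED_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})
#: pairs that pay the terminal penalty at helix ends
WEAK_PAIRS = frozenset({"AU", "UA", "GU", "UG"})

MAX_TABULATED = 30

_REQUIRED_SECTIONS = (
    "meta",
    "stack",
    "hairpin_len",
    "bulge_len",
    "internal_len",
    "multiloop",
    "terminal_au",
    "ln_coeff",
)


class ParameterError(ValueError):
    """A parameter file is malformed or incomplete."""


class IncompatibleStructureError(ValueError):
    """A structure contains a pair the model does not allow for the sequence."""


@dataclass(frozen=True)
class NNParameterSet:
    """A loaded nearest-neighbor parameter set (all energies in kcal/mol)."""

    name: str
    rt: float  # kcal/mol, 0.6163 at 37 degC
    stack: dict[tuple[str, str], float]  # (closing pair, inner pair) -> dG
    hairpin_len: tuple[float, ...]  # index = unpaired bases in the loop, 0..30
    bulge_len: tuple[float, ...]
    internal_len: tuple[float, ...]
    multiloop_a: float
    multiloop_b: float  # per branch, closing pair included
    multiloop_c: float  # per unpaired base
    terminal_au: float
    ln_coeff: float  # long-loop extrapolation coefficient

    def __post_init__(self) -> None:
        for arr, label in (
            (self.hairpin_len, "hairpin_len"),
            (self.bulge_len, "bulge_len"),
            (self.internal_len, "internal_len"),
        ):
            if len(arr) != MAX_TABULATED + 1:
                raise ParameterError(
                    f"{label} must tabulate lengths 0..{MAX_TABULATED} "
                    f"({MAX_TABULATED + 1} values), got {len(arr)}"
                )
        missing = {
            (o, i) for o in ALLOWED_PAIRS for i in ALLOWED_PAIRS
        } - set(self.stack)
        if missing:
            raise ParameterError(f"stack table missing entries: {sorted(missing)[:4]}...")

    # -- lookups ----------------------------------------------------------

    def stack_energy(self, closing: str, inner: str) -> float:
        if closing not in ALLOWED_PAIRS or inner not in ALLOWED_PAIRS:
            raise IncompatibleStructureError(
                f"stack lookup on disallowed pair {closing!r}/{inner!r}"
            )
        return self.stack[(closing, inner)]

    def _extrapolate(self, table: tuple[float, ...], size: int) -> float:
        if size <= MAX_TABULATED:
            return table[size]
        return table[MAX_TABULATED] + self.ln_coeff * math.log(size / MAX_TABULATED)

    def hairpin_energy(self, size: int) -> float:
        return self._extrapolate(self.hairpin_len, size)

    def bulge_energy(self, size: int) -> float:
        return self._extrapolate(self.bulge_len, size)

    def internal_energy(self, size: int) -> float:
        return self._extrapolate(self.internal_len, size)

    def terminal_penalty(self, pair: str) -> float:
        return self.terminal_au if pair in WEAK_PAIRS else 0.0


def _pairs_sorted(d: dict[tuple[str, str], float]):
    return {o: {i: d[(o, i)] for i in sorted(ALLOWED_PAIRS)} for o in sorted(ALLOWED_PAIRS)}


def write_parameters(params: NNParameterSet, path) -> None:
    doc = {
        "meta": {"name": params.name, "RT": params.rt},
        "stack": _pairs_sorted(params.stack),
        "hairpin_len": list(params.hairpin_len),
        "bulge_len": list(params.bulge_len),
        "internal_len": list(params.internal_len),
        "multiloop": {"a": params.multiloop_a, "b": params.multiloop_b, "c": params.multiloop_c},
        "terminal_au": params.terminal_au,
        "ln_coeff": params.ln_coeff,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _params_from_doc(doc: dict, source: str) -> NNParameterSet:
    missing = [s for s in _REQUIRED_SECTIONS if s not in doc]
    if missing:
        raise ParameterError(f"{source}: missing section(s) {missing}")
    unknown = set(doc) - set(_REQUIRED_SECTIONS)
    if unknown:
        raise ParameterError(f"{source}: unknown section(s) {sorted(unknown)}")
    try:
        stack = {
            (o, i): float(v)
            for o, row in doc["stack"].items()
            for i, v in row.items()
        }
        ml = doc["multiloop"]
        return NNParameterSet(
            name=str(doc["meta"]["name"]),
            rt=float(doc["meta"]["RT"]),
            stack=stack,
            hairpin_len=tuple(float(x) for x in doc["hairpin_len"]),
            bulge_len=tuple(float(x) for x in doc["bulge_len"]),
            internal_len=tuple(float(x) for x in doc["internal_len"]),
            multiloop_a=float(ml["a"]),
            multiloop_b=float(ml["b"]),
            multiloop_c=float(ml["c"]),
            terminal_au=float(doc["terminal_au"]),
            ln_coeff=float(doc["ln_coeff"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"{source}: {exc}") from exc


def load_parameters(path) -> NNParameterSet:
    """Load a parameter set from its JSON schema (see module docstring)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParameterError(f"{path.name}: not valid JSON ({exc})") from exc
    return _params_from_doc(doc, path.name)


def load_default(name: str = "toy37") -> NNParameterSet:
    """Load a packaged parameter set (``toy37`` or ``toy37_alt``)."""
    ref = resources.files("foldeval.data").joinpath(f"{name}.json")
    try:
        doc = json.loads(ref.read_text())
    except FileNotFoundError as exc:
        raise ParameterError(f"no packaged parameter set named {name!r}") from exc
    return _params_from_doc(doc, f"{name}.json")


# ---------------------------------------------------------------------------
# loop decomposition and energy evaluation


@dataclass(frozen=True)
class Loop:
    """One loop of the decomposition.

    ``closing`` is the outer pair (None for the exterior loop), ``branches``
    the directly nested pairs, ``unpaired`` the number of single-stranded
    bases on the loop.
    """

    kind: str  # hairpin | stack | bulge | internal | multiloop | exterior
    closing: tuple[int, int] | None
    branches: tuple[tuple[int, int], ...]
    unpaired: int


def loop_decomposition(structure: SecondaryStructure) -> list[Loop]:
    """Decompose a structure into its loops (exterior loop always present)."""
    ordered = sorted(structure.pairs)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in ordered:
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(pair)
        children.setdefault(pair, [])
        stack.append(pair)

    loops: list[Loop] = []
    ext_branches = tuple(children[None])
    ext_unpaired = structure.length - sum(j - i + 1 for i, j in ext_branches)
    loops.append(Loop("exterior", None, ext_branches, ext_unpaired))
    for pair in ordered:
        i, j = pair
        kids = tuple(children[pair])
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
        if not kids:
            kind = "hairpin"
        elif len(kids) == 1:
            k, l = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                kind = "stack"
            elif left == 0 or right == 0:
                kind = "bulge"
            else:
                kind = "internal"
        else:
            kind = "multiloop"
        loops.append(Loop(kind, pair, kids, unpaired))
    return loops


def _pair_str(seq: str, pair: tuple[int, int]) -> str:
    return seq[pair[0]] + seq[pair[1]]


def loop_energy(loop: Loop, sequence: RnaSequence, params: NNParameterSet) -> float:
    """Energy of a single loop (kcal/mol) under the module's conventions."""
    s = sequence.residues
    if loop.kind == "exterior":
        return sum(params.terminal_penalty(_pair_str(s, b)) for b in loop.branches)
    closing = _pair_str(s, loop.closing)
    if loop.kind == "hairpin":
        return params.hairpin_energy(loop.unpaired) + params.terminal_penalty(closing)
    if loop.kind == "stack":
        return params.stack_energy(closing, _pair_str(s, loop.branches[0]))
    if loop.kind in ("bulge", "internal"):
        inner = _pair_str(s, loop.branches[0])
        size_fn = params.bulge_energy if loop.kind == "bulge" else params.internal_energy
        return (
            size_fn(loop.unpaired)
            + params.terminal_penalty(closing)
            + params.terminal_penalty(inner)
        )
    # multiloop
    e = (
        params.multiloop_a
        + params.multiloop_b * (len(loop.branches) + 1)
        + params.multiloop_c * loop.unpaired
        + params.terminal_penalty(closing)
    )
    return e + sum(params.terminal_penalty(_pair_str(s, b)) for b in loop.branches)


def free_energy(
    sequence: RnaSequence, structure: SecondaryStructure, params: NNParameterSet
) -> float:
    """Free energy of ``structure`` on ``sequence`` (kcal/mol).

    Exactly the sum of per-loop energies; the empty structure is 0.0.
    """
    if structure.length != sequence.length:
        raise StructureError("sequence/structure length mismatch")
    for i, j in structure.pairs:
        pr = sequence.residues[i] + sequence.residues[j]
        if pr not in ALLOWED_PAIRS:
            raise IncompatibleStructureError(
                f"pair ({i},{j}) = {pr} is not an allowed base pair"
            )
    return sum(loop_energy(lp, sequence, params) for lp in loop_decomposition(structure))
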