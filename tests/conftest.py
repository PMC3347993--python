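import numpy as np
import pytest

from foldeval.energy_model import load_default
from foldeval.structure_io import MIN_HAIRPIN, RnaSequence, SecondaryStructure


@pytest.fixture(scope="session")
def toy37():
    return load_default("toy37")


@pytest.fixture(scope="session")
def toy37_alt():
    return load_default("toy37_alt")


def random_rna(rng: np.random.Generator, n: int) -> RnaSequence:
    return RnaSequence(id="rnd", residues="".join(rng.choice(list("ACGU"), n)))


def random_structure(rng: np.random.Generator, n: int, density: float = 0.6
                     ) -> SecondaryStructure:
    """A random valid (nested, min-hairpin) structure over n positions,
    ignoring sequence compatibility."""
    candidates = [(i, j) for i in range(n) for j in range(i + MIN_HAIRPIN + 1, n)]
    pairs: set[tuple[int, int]] = set()
    used: set[int] = set()
    for idx in rng.permutation(len(candidates)):
        i, j = candidates[idx]
        if rng.random() > density:
            continue
        if i in used or j in used:
            continue
        if any(k < i < l < j or i < k < j < l for k, l in pairs):
            continue
        pairs.add((i, j))
        used.update((i, j))
    return SecondaryStructure(length=n, pairs=frozenset(pairs))
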