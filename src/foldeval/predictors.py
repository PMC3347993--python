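"""Secondary-structure predictors over a nearest-neighbor energy model.

Implements the four estimators compared throughout the package:

* :func:`mfe_fold` — minimum-free-energy folding (Zuker-style dynamic
  program over the reduced model in :mod:`foldeval.energy_model`);
* :func:`mea_fold` — maximum expected accuracy: maximises
  ``sum_{(i,j) in S} 2*gamma*p(i,j) + sum_{i unpaired} q(i)`` over valid
  structures, from a base-pair probability matrix;
* :func:`centroid_fold` — the gamma-centroid estimator: maximises
  ``sum_{(i,j) in S} ((gamma+1)*p(i,j) - 1)``, so only pairs with
  ``p > 1/(gamma+1)`` can contribute;
* :func:`pseudo_mea_fold` — centroid folding with gamma selected
  automatically by maximising the pseudo-expected F-measure computed from
  the probability matrix alone (:func:`pseudo_expected_accuracy`).

Base-pair probabilities come from a McCaskill-style inside-outside
computation (:func:`partition_function`, :func:`basepair_probabilities`),
carried in log space so long sequences do not overflow.

:func:`enumerate_structures` exhaustively lists all valid structures of a
short sequence; the test suite uses it as an independent oracle for every
dynamic program here.

Determinism: all tracebacks break ties in a fixed order — prefer leaving a
base unpaired, then prefer the pair with smaller ``i``, then smaller ``j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .energy_model import ALLOWED_PAIRS, NNParameterSet
from .structure_io import MIN_HAIRPIN, RnaSequence, SecondaryStructure

__all__ = [
    "FoldConfig",
    "BasePairProbMatrix",
    "FoldResult",
    "PartitionResult",
    "DEFAULT_GAMMA_GRID",
    "enumerate_structures",
    "mfe_fold",
    "partition_function",
    "basepair_probabilities",
    "mea_fold",
    "centroid_fold",
    "mea_score",
    "centroid_score",
    "pseudo_expected_accuracy",
    "pseudo_mea_fold",
]

_NEG_INF = -np.inf
_SPAN = MIN_HAIRPIN + 1  # minimal j - i for a pair

#: gamma grid for pseudo-expected-accuracy maximisation: 2^-5 .. 2^10
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 11))


@dataclass(frozen=True)
class FoldConfig:
    """Tunables of the folding dynamic programs."""

    internal_loop_cap: int = 30  # max unpaired bases in a bulge/internal loop


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    algorithm: str  # mfe | mea | centroid | pseudo_mea
    score: float  # kcal/mol for mfe, objective value otherwise
    gamma: float | None = None


@dataclass
class BasePairProbMatrix:
    """Symmetric matrix of base-pair probabilities ``p(i, j)``.

    ``q(i) = 1 - sum_j p(i, j)`` is the probability that base ``i`` is
    unpaired.  Entries closer to the diagonal than the minimum hairpin span
    are zero.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = self.n
        if self.p.shape != (n, n):
            raise ValueError("probability matrix must be square")
        if not np.allclose(self.p, self.p.T, atol=1e-9):
            raise ValueError("probability matrix must be symmetric")
        if self.p.min() < -1e-9 or self.p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        band = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) < _SPAN
        if np.any(self.p[band] != 0):
            raise ValueError(f"p(i,j) must be 0 for |j - i| < {_SPAN}")
        if (self.p.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("row sums of p must not exceed 1")

    @property
    def n(self) -> int:
        return self.p.shape[0]

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)

    # interoperability: 1-based upper-triangle triples
    def to_triples(self) -> str:
        lines = []
        for i, j in zip(*np.nonzero(np.triu(self.p))):
            lines.append(f"{i + 1}\t{j + 1}\t{self.p[i, j]:.10g}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_triples(cls, text: str, n: int) -> "BasePairProbMatrix":
        p = np.zeros((n, n))
        for line in text.splitlines():
            if not line.strip():
                continue
            i_s, j_s, v_s = line.split("\t")
            i, j = int(i_s) - 1, int(j_s) - 1
            p[i, j] = p[j, i] = float(v_s)
        return cls(p)


@dataclass
class PartitionResult:
    """Partition function of a sequence (``Z`` in linear, ``logZ`` in log space)."""

    logZ: float
    _tables: "_DPTables" = field(repr=False)

    @property
    def Z(self) -> float:
        return math.exp(self.logZ)


# ---------------------------------------------------------------------------
# exhaustive enumeration (test oracle)

MAX_ENUM_LENGTH = 16


def enumerate_structures(sequence: RnaSequence, max_length: int = MAX_ENUM_LENGTH):
    """All valid secondary structures of a short sequence.

    Valid means: pairs drawn from the allowed pair set, pseudoknot-free,
    hairpin loops of at least three unpaired bases.  Guarded to
    ``max_length`` to avoid combinatorial explosion.
    """
    n = sequence.length
    if n > max_length:
        raise ValueError(f"enumeration limited to length {max_length}, got {n}")
    s = sequence.residues
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i < _SPAN:
            return [frozenset()]
        key = (i, j)
        if key not in memo:
            out = [fs for fs in rec(i + 1, j)]
            for k in range(i + _SPAN, j + 1):
                if s[i] + s[k] in ALLOWED_PAIRS:
                    for inner in rec(i + 1, k - 1):
                        for rest in rec(k + 1, j):
                            out.append(inner | rest | {(i, k)})
            memo[key] = out
        return memo[key]

    return [SecondaryStructure(length=n, pairs=fs) for fs in rec(0, n - 1)]


# ---------------------------------------------------------------------------
# shared DP precomputation


class _DPTables:
    """Per-(sequence, params, config) tables shared by the folding DPs."""

    def __init__(self, sequence: RnaSequence, params: NNParameterSet, config: FoldConfig):
        self.sequence = sequence
        self.params = params
        self.config = config
        s = sequence.residues
        n = self.n = sequence.length
        self.rt = params.rt

        allowed = np.zeros((n, n), dtype=bool)
        wau = np.zeros((n, n))
        for i in range(n):
            for j in range(i + _SPAN, n):
                pr = s[i] + s[j]
                if pr in ALLOWED_PAIRS:
                    allowed[i, j] = True
                    wau[i, j] = params.terminal_penalty(pr)
        self.allowed = allowed
        self.wau = wau

        # stack energy closing (i,j) over inner (i+1,j-1); only meaningful
        # where both pairs are allowed
        stk = np.zeros((n, n))
        for i in range(n):
            for j in range(i + _SPAN + 2, n):
                if allowed[i, j] and allowed[i + 1, j - 1]:
                    stk[i, j] = params.stack_energy(s[i] + s[j], s[i + 1] + s[j - 1])
        self.stack_e = stk

        self.hp_e = np.array([params.hairpin_energy(k) for k in range(n + 1)])

        # internal/bulge candidates: unpaired counts (d1, d2) on each side,
        # 1 <= d1+d2 <= cap, with the size-dependent loop penalty
        cap = config.internal_loop_cap
        d1s, d2s, ebase = [], [], []
        for d1 in range(0, cap + 1):
            for d2 in range(0, cap + 1 - d1):
                if d1 == d2 == 0:
                    continue
                d1s.append(d1)
                d2s.append(d2)
                size = d1 + d2
                ebase.append(
                    params.bulge_energy(size) if 0 in (d1, d2) else params.internal_energy(size)
                )
        self.il_d1 = np.array(d1s, dtype=int)
        self.il_d2 = np.array(d2s, dtype=int)
        self.il_e = np.array(ebase)

        self.ml_a = params.multiloop_a
        self.ml_b = params.multiloop_b
        self.ml_c = params.multiloop_c

        self._mfe_done = False
        self._inside_done = False
        self._outside_done = False

    # -- internal-loop candidate views ------------------------------------

    def _il_candidates(self, i: int, j: int):
        """(k, l, loop energy) arrays of bulge/internal transitions under (i, j)."""
        ks = i + 1 + self.il_d1
        ls = j - 1 - self.il_d2
        ok = ls - ks >= _SPAN
        return ks[ok], ls[ok], self.il_e[ok]

    # -- MFE ---------------------------------------------------------------

    def run_mfe(self) -> None:
        if self._mfe_done:
            return
        n, rt = self.n, self.rt
        inf = np.inf
        V = np.full((n, n), inf)
        WM1 = np.full((n, n), inf)
        WM = np.full((n, n), inf)
        b, c = self.ml_b, self.ml_c
        for d in range(_SPAN, n):
            for i in range(n - d):
                j = i + d
                if self.allowed[i, j]:
                    best = self.hp_e[d - 1] + self.wau[i, j]
                    if self.allowed[i + 1, j - 1]:
                        best = min(best, self.stack_e[i, j] + V[i + 1, j - 1])
                    ks, ls, eb = self._il_candidates(i, j)
                    if ks.size:
                        cand = V[ks, ls] + (eb + self.wau[i, j] + self.wau[ks, ls])
                        m = cand.min()
                        if m < best:
                            best = m
                    if d >= 2 * _SPAN + 3:
                        kk = np.arange(i + _SPAN + 2, j - _SPAN)
                        if kk.size:
                            cand = WM[i + 1, kk - 1] + WM1[kk, j - 1]
                            m = cand.min() + (self.ml_a + b + self.wau[i, j])
                            if m < best:
                                best = m
                    V[i, j] = best
                # WM1: one branch starting at i, trailing unpaired to j
                ls1 = np.arange(i + _SPAN, j + 1)
                WM1[i, j] = np.min(V[i, ls1] + b + self.wau[i, ls1] + c * (j - ls1))
                # WM: at least one branch in [i, j]
                kk = np.arange(i, j - _SPAN + 1)
                best_m = np.min(c * (kk - i) + WM1[kk, j])
                kk2 = np.arange(i + _SPAN + 1, j - _SPAN + 1)
                if kk2.size:
                    best_m = min(best_m, np.min(WM[i, kk2 - 1] + WM1[kk2, j]))
                WM[i, j] = best_m
        W = np.zeros(n + 1)
        for j in range(n):
            best = W[j]
            kk = np.arange(0, j - _SPAN + 1)
            if kk.size:
                cand = W[kk] + V[kk, j] + self.wau[kk, j]
                best = min(best, cand.min())
            W[j + 1] = best
        self.V, self.WM1, self.WM, self.W = V, WM1, WM, W
        self._mfe_done = True

    def mfe_traceback(self) -> set[tuple[int, int]]:
        self.run_mfe()
        V, WM1, WM, W = self.V, self.WM1, self.WM, self.W
        b, c = self.ml_b, self.ml_c
        pairs: set[tuple[int, int]] = set()
        tasks: list[tuple] = [("W", self.n - 1)]
        while tasks:
            task = tasks.pop()
            if task[0] == "W":
                j = task[1]
                while j >= 0:
                    if W[j + 1] == W[j]:
                        j -= 1
                        continue
                    for k in range(0, j - _SPAN + 1):
                        if W[j + 1] == W[k] + V[k, j] + self.wau[k, j]:
                            pairs.add((k, j))
                            tasks.append(("V", k, j))
                            j = k - 1
                            break
                    else:  # pragma: no cover - defensive
                        raise AssertionError("exterior traceback failed")
            elif task[0] == "V":
                _, i, j = task
                target = V[i, j]
                if target == self.hp_e[j - i - 1] + self.wau[i, j]:
                    continue
                if (
                    self.allowed[i + 1, j - 1]
                    and target == self.stack_e[i, j] + V[i + 1, j - 1]
                ):
                    pairs.add((i + 1, j - 1))
                    tasks.append(("V", i + 1, j - 1))
                    continue
                ks, ls, eb = self._il_candidates(i, j)
                hit = False
                order = np.lexsort((ls, ks))
                for idx in order:
                    k, l = int(ks[idx]), int(ls[idx])
                    if target == V[k, l] + (eb[idx] + self.wau[i, j] + self.wau[k, l]):
                        pairs.add((k, l))
                        tasks.append(("V", k, l))
                        hit = True
                        break
                if hit:
                    continue
                for k in range(i + _SPAN + 2, j - _SPAN):
                    if target == WM[i + 1, k - 1] + WM1[k, j - 1] + (
                        self.ml_a + b + self.wau[i, j]
                    ):
                        tasks.append(("WM", i + 1, k - 1))
                        tasks.append(("WM1", k, j - 1))
                        hit = True
                        break
                if not hit:  # pragma: no cover - defensive
                    raise AssertionError(f"V traceback failed at ({i},{j})")
            elif task[0] == "WM1":
                _, i, j = task
                target = WM1[i, j]
                for l in range(i + _SPAN, j + 1):
                    if target == V[i, l] + b + self.wau[i, l] + c * (j - l):
                        pairs.add((i, l))
                        tasks.append(("V", i, l))
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError("WM1 traceback failed")
            else:  # WM
                _, i, j = task
                target = WM[i, j]
                hit = False
                for k in range(i, j - _SPAN + 1):
                    if target == c * (k - i) + WM1[k, j]:
                        tasks.append(("WM1", k, j))
                        hit = True
                        break
                if not hit:
                    for k in range(i + _SPAN + 1, j - _SPAN + 1):
                        if target == WM[i, k - 1] + WM1[k, j]:
                            tasks.append(("WM", i, k - 1))
                            tasks.append(("WM1", k, j))
                            hit = True
                            break
                if not hit:  # pragma: no cover - defensive
                    raise AssertionError("WM traceback failed")
        return pairs

    # -- inside (partition function) ---------------------------------------

    def run_inside(self) -> None:
        if self._inside_done:
            return
        n, rt = self.n, self.rt
        LZb = np.full((n, n), _NEG_INF)
        LM1 = np.full((n, n), _NEG_INF)
        LM = np.full((n, n), _NEG_INF)
        b, c = self.ml_b, self.ml_c
        for d in range(_SPAN, n):
            for i in range(n - d):
                j = i + d
                if self.allowed[i, j]:
                    terms = [-(self.hp_e[d - 1] + self.wau[i, j]) / rt]
                    if self.allowed[i + 1, j - 1] and LZb[i + 1, j - 1] > _NEG_INF:
                        terms.append(-self.stack_e[i, j] / rt + LZb[i + 1, j - 1])
                    ks, ls, eb = self._il_candidates(i, j)
                    if ks.size:
                        cand = LZb[ks, ls] - (eb + self.wau[i, j] + self.wau[ks, ls]) / rt
                        terms.append(logsumexp(cand))
                    if d >= 2 * _SPAN + 3:
                        kk = np.arange(i + _SPAN + 2, j - _SPAN)
                        if kk.size:
                            cand = LM[i + 1, kk - 1] + LM1[kk, j - 1]
                            terms.append(
                                logsumexp(cand) - (self.ml_a + b + self.wau[i, j]) / rt
                            )
                    LZb[i, j] = logsumexp(terms)
                ls1 = np.arange(i + _SPAN, j + 1)
                LM1[i, j] = logsumexp(
                    LZb[i, ls1] - (b + self.wau[i, ls1] + c * (j - ls1)) / rt
                )
                kk = np.arange(i, j - _SPAN + 1)
                lm = logsumexp(-c * (kk - i) / rt + LM1[kk, j])
                kk2 = np.arange(i + _SPAN + 1, j - _SPAN + 1)
                if kk2.size:
                    lm = np.logaddexp(lm, logsumexp(LM[i, kk2 - 1] + LM1[kk2, j]))
                LM[i, j] = lm
        # prefix exterior: LW[k] = log partition of s[0..k-1]
        LW = np.zeros(n + 1)
        for j in range(n):
            val = LW[j]
            kk = np.arange(0, j - _SPAN + 1)
            if kk.size:
                val = np.logaddexp(
                    val, logsumexp(LW[kk] + LZb[kk, j] - self.wau[kk, j] / rt)
                )
            LW[j + 1] = val
        # suffix exterior: LWR[k] = log partition of s[k..n-1]
        LWR = np.zeros(n + 1)
        for i in range(n - 1, -1, -1):
            val = LWR[i + 1]
            ll = np.arange(i + _SPAN, n)
            if ll.size:
                val = np.logaddexp(
                    val, logsumexp(LZb[i, ll] - self.wau[i, ll] / rt + LWR[ll + 1])
                )
            LWR[i] = val
        self.LZb, self.LM1, self.LM, self.LW, self.LWR = LZb, LM1, LM, LW, LWR
        self.logZ = float(LW[n])
        self._inside_done = True

    # -- outside (pair probabilities) --------------------------------------

    def run_outside(self) -> None:
        if self._outside_done:
            return
        self.run_inside()
        n, rt = self.n, self.rt
        LZb, LM, LW, LWR = self.LZb, self.LM, self.LW, self.LWR
        b, c = self.ml_b, self.ml_c
        LO = np.full((n, n), _NEG_INF)
        for d in range(n - 1, _SPAN - 1, -1):
            for i in range(n - d):
                j = i + d
                if not self.allowed[i, j]:
                    continue
                terms = [LW[i] + LWR[j + 1] - self.wau[i, j] / rt]
                if i > 0 and j < n - 1 and self.allowed[i - 1, j + 1]:
                    terms.append(LO[i - 1, j + 1] - self.stack_e[i - 1, j + 1] / rt)
                # inner pair of a bulge/internal loop closed by (p, q)
                ps = i - 1 - self.il_d1
                qs = j + 1 + self.il_d2
                ok = (ps >= 0) & (qs < n)
                if ok.any():
                    ps_, qs_, eb_ = ps[ok], qs[ok], self.il_e[ok]
                    cand = LO[ps_, qs_] - (
                        eb_ + self.wau[ps_, qs_] + self.wau[i, j]
                    ) / rt
                    terms.append(logsumexp(cand))
                # branch of a multiloop closed by (p, q): the rest of the
                # loop must hold at least one other branch
                if i > 0 and j < n - 1:
                    P = np.arange(0, i)
                    Q = np.arange(j + 1, n)
                    # left of the branch: >=1 branch (A1) or all unpaired (A2)
                    A1 = np.full(i, _NEG_INF)
                    m = P + 1 <= i - 1
                    if m.any():
                        A1[m] = LM[P[m] + 1, i - 1]
                    A2 = -c * (i - 1 - P) / rt
                    B1 = np.full(n - 1 - j, _NEG_INF)  # LM on [j+1, q-1]
                    m = Q - 1 >= j + 1
                    if m.any():
                        B1[m] = LM[j + 1, Q[m] - 1]
                    BU = -c * (Q - 1 - j) / rt
                    B1u = np.logaddexp(B1, BU)  # >=0 branches on the right
                    inner = np.logaddexp(
                        A1[:, None] + B1u[None, :], A2[:, None] + B1[None, :]
                    )
                    sub = (
                        LO[np.ix_(P, Q)]
                        + inner
                        - (
                            self.ml_a
                            + 2 * b
                            + self.wau[np.ix_(P, Q)]
                            + self.wau[i, j]
                        )
                        / rt
                    )
                    t = logsumexp(sub)
                    if t > _NEG_INF:
                        terms.append(t)
                LO[i, j] = logsumexp(terms)
        self.LO = LO
        self._outside_done = True

    def pair_probabilities(self) -> np.ndarray:
        self.run_outside()
        n = self.n
        lp = self.LZb + self.LO - self.logZ
        p = np.zeros((n, n))
        mask = self.allowed
        p[mask] = np.exp(lp[mask])
        p = np.clip(p, 0.0, 1.0)
        return p + p.T

    # -- Boltzmann sampling (used by the synthetic-data generator) ---------

    def sample_pairs(self, rng: np.random.Generator) -> set[tuple[int, int]]:
        """Draw one structure with probability exp(-E/RT)/Z (stochastic traceback)."""
        self.run_inside()
        LZb, LM1, LM, LW = self.LZb, self.LM1, self.LM, self.LW
        rt, b, c = self.rt, self.ml_b, self.ml_c
        pairs: set[tuple[int, int]] = set()

        def choose(options, total):
            """options: iterable of (log weight, payload); total: log normaliser."""
            u = rng.random()
            acc = 0.0
            last = None
            for lw, payload in options:
                if lw == _NEG_INF:
                    continue
                acc += math.exp(lw - total)
                last = payload
                if u < acc:
                    return payload
            return last

        def sample_b(i: int, j: int) -> None:
            pairs.add((i, j))
            opts = [(-(self.hp_e[j - i - 1] + self.wau[i, j]) / rt, ("hp",))]
            if self.allowed[i + 1, j - 1]:
                opts.append(
                    (-self.stack_e[i, j] / rt + LZb[i + 1, j - 1], ("il", i + 1, j - 1))
                )
            ks, ls, eb = self._il_candidates(i, j)
            for k, l, e in zip(ks, ls, eb):
                opts.append(
                    (
                        LZb[k, l] - (e + self.wau[i, j] + self.wau[k, l]) / rt,
                        ("il", int(k), int(l)),
                    )
                )
            for k in range(i + _SPAN + 2, j - _SPAN):
                opts.append(
                    (
                        LM[i + 1, k - 1]
                        + LM1[k, j - 1]
                        - (self.ml_a + b + self.wau[i, j]) / rt,
                        ("ml", k),
                    )
                )
            pick = choose(opts, LZb[i, j])
            if pick[0] == "il":
                sample_b(pick[1], pick[2])
            elif pick[0] == "ml":
                k = pick[1]
                sample_m(i + 1, k - 1)
                sample_m1(k, j - 1)

        def sample_m1(i: int, j: int) -> None:
            opts = [
                (LZb[i, l] - (b + self.wau[i, l] + c * (j - l)) / rt, l)
                for l in range(i + _SPAN, j + 1)
            ]
            l = choose(opts, LM1[i, j])
            sample_b(i, l)

        def sample_m(i: int, j: int) -> None:
            opts = [
                (-c * (k - i) / rt + LM1[k, j], ("one", k))
                for k in range(i, j - _SPAN + 1)
            ]
            opts += [
                (LM[i, k - 1] + LM1[k, j], ("more", k))
                for k in range(i + _SPAN + 1, j - _SPAN + 1)
            ]
            kind, k = choose(opts, LM[i, j])
            if kind == "more":
                sample_m(i, k - 1)
            sample_m1(k, j)

        j = self.n - 1
        while j >= 0:
            opts = [(LW[j], ("un",))]
            opts += [
                (LW[k] + LZb[k, j] - self.wau[k, j] / rt, ("pair", k))
                for k in range(0, j - _SPAN + 1)
            ]
            pick = choose(opts, LW[j + 1])
            if pick[0] == "un":
                j -= 1
            else:
                k = pick[1]
                sample_b(k, j)
                j = k - 1
        return pairs


def _tables(sequence, params, config):
    return _DPTables(sequence, params, config or FoldConfig())


# ---------------------------------------------------------------------------
# public operations


def mfe_fold(
    sequence: RnaSequence, params: NNParameterSet, config: FoldConfig | None = None
) -> FoldResult:
    """Minimum-free-energy structure of ``sequence`` (deterministic traceback)."""
    t = _tables(sequence, params, config)
    t.run_mfe()
    pairs = t.mfe_traceback()
    structure = SecondaryStructure(length=sequence.length, pairs=frozenset(pairs))
    return FoldResult(structure=structure, algorithm="mfe", score=float(t.W[t.n]))


def partition_function(
    sequence: RnaSequence, params: NNParameterSet, config: FoldConfig | None = None
) -> PartitionResult:
    """Boltzmann partition function ``Z = sum_S exp(-E(S)/RT)`` (log-space)."""
    t = _tables(sequence, params, config)
    t.run_inside()
    return PartitionResult(logZ=t.logZ, _tables=t)


def basepair_probabilities(
    sequence: RnaSequence, params: NNParameterSet, config: FoldConfig | None = None
) -> BasePairProbMatrix:
    """Equilibrium base-pair probabilities via the inside-outside algorithm."""
    t = _tables(sequence, params, config)
    return BasePairProbMatrix(t.pair_probabilities())


# -- estimators on probability matrices -------------------------------------


def _max_weight_structure(gain: np.ndarray, unpaired: np.ndarray):
    """Maximise ``sum gain(i,j) + sum unpaired(i)`` over valid structures.

    Nussinov-style DP; ties broken by preferring unpaired, then smaller i,
    then smaller j.  Returns (score, pair set).
    """
    n = gain.shape[0]
    if n == 0:
        return 0.0, set()
    M = np.zeros((n, n))

    def m(i: int, j: int) -> float:
        return M[i, j] if j >= i else 0.0

    for d in range(0, n):
        for i in range(n - d):
            j = i + d
            best = m(i, j - 1) + unpaired[j]
            ks = np.arange(i, j - _SPAN + 1)
            if ks.size:
                left = np.concatenate(([0.0], M[i, ks[1:] - 1]))
                inner = M[ks + 1, j - 1]
                cand = left + gain[ks, j] + inner
                mx = cand.max()
                if mx > best:
                    best = mx
            M[i, j] = best
    pairs: set[tuple[int, int]] = set()
    tasks = [(0, n - 1)]
    while tasks:
        i, j = tasks.pop()
        while j >= i:
            if M[i, j] == m(i, j - 1) + unpaired[j]:
                j -= 1
                continue
            hit = False
            for k in range(i, j - _SPAN + 1):
                if M[i, j] == m(i, k - 1) + gain[k, j] + m(k + 1, j - 1):
                    pairs.add((k, j))
                    tasks.append((k + 1, j - 1))
                    j = k - 1
                    hit = True
                    break
            if not hit:  # pragma: no cover - defensive
                raise AssertionError("pairing traceback failed")
    return float(M[0, n - 1]), pairs


def mea_score(P: BasePairProbMatrix, structure: SecondaryStructure, gamma: float) -> float:
    """The MEA objective of a given structure (brute-force evaluation)."""
    q = P.q
    paired = set()
    total = 0.0
    for i, j in structure.pairs:
        total += 2.0 * gamma * P.p[i, j]
        paired.update((i, j))
    total += sum(q[i] for i in range(P.n) if i not in paired)
    return total


def centroid_score(
    P: BasePairProbMatrix, structure: SecondaryStructure, gamma: float
) -> float:
    """The gamma-centroid objective of a given structure."""
    return sum((gamma + 1.0) * P.p[i, j] - 1.0 for i, j in structure.pairs)


def mea_fold(P: BasePairProbMatrix, gamma: float = 1.0) -> FoldResult:
    """Maximum-expected-accuracy structure from a probability matrix."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = P.n
    gain = np.where(
        np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= _SPAN,
        2.0 * gamma * P.p,
        _NEG_INF,
    )
    score, pairs = _max_weight_structure(gain, P.q)
    return FoldResult(
        structure=SecondaryStructure(length=n, pairs=frozenset(pairs)),
        algorithm="mea",
        score=score,
        gamma=gamma,
    )


def centroid_fold(P: BasePairProbMatrix, gamma: float = 1.0) -> FoldResult:
    """Gamma-centroid structure: only pairs with ``p > 1/(gamma+1)`` can help."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = P.n
    gain = np.where(
        np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= _SPAN,
        (gamma + 1.0) * P.p - 1.0,
        _NEG_INF,
    )
    score, pairs = _max_weight_structure(gain, np.zeros(n))
    return FoldResult(
        structure=SecondaryStructure(length=n, pairs=frozenset(pairs)),
        algorithm="centroid",
        score=score,
        gamma=gamma,
    )


def pseudo_expected_accuracy(
    P: BasePairProbMatrix, structure: SecondaryStructure
) -> tuple[float, float, float]:
    """Pseudo sensitivity / PPV / F of a structure, from probabilities alone.

    ``eTP = sum_{(i,j) in S} p(i,j)`` plays the role of the true-positive
    count; the reference "pair count" is the total pair mass
    ``sum_{i<j} p(i,j)`` and the prediction size is ``|S|``.  Corner
    conventions match :func:`foldeval.accuracy_metrics.compare`.
    """
    etp = float(sum(P.p[i, j] for i, j in structure.pairs))
    mass = float(np.triu(P.p).sum())
    npred = len(structure.pairs)
    if mass == 0 and npred == 0:
        return 1.0, 1.0, 1.0
    sens = etp / mass if mass > 0 else 0.0
    ppv = etp / npred if npred > 0 else 0.0
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else 0.0
    return sens, ppv, f


def pseudo_mea_fold(
    P: BasePairProbMatrix, gamma_grid=DEFAULT_GAMMA_GRID
) -> FoldResult:
    """Centroid folding with gamma chosen to maximise pseudo-expected F.

    Scans the grid, keeps the gamma with the best pseudo-F (ties to the
    smaller gamma), and returns that centroid structure.
    """
    grid = list(gamma_grid)
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    best = None
    for gamma in sorted(grid):
        res = centroid_fold(P, gamma)
        _, _, f = pseudo_expected_accuracy(P, res.structure)
        if best is None or f > best[0]:
            best = (f, gamma, res)
    _, gamma, res = best
    return FoldResult(
        structure=res.structure, algorithm="pseudo_mea", score=best[0], gamma=gamma
    )
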