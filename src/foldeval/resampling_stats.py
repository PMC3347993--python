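"""Bootstrap percentile confidence intervals and permutation tests.

The resampling unit is the individual RNA record: a dataset-level CI on an
average F-measure resamples per-record values with replacement (class
labels carried along when a class-aware average is requested) and
recomputes the average on every resample.  Interval bounds are empirical
order-statistic percentiles with linear interpolation, so results are
bit-stable for a fixed seed.

The permutation test compares two sets of per-record values by the
difference of their means, against the null distribution obtained by
re-splitting the pooled values into sets of the original sizes.  The
one-sided orientation must be stated explicitly: ``alternative="A_less"``
asks for evidence that set A's mean is below set B's (p = fraction of
permuted differences <= the observed one), ``"A_greater"`` the mirror
image.  By default the p-value is the plain proportion, which can be
exactly 0; ``plus_one=True`` switches to the (k+1)/(N+1) estimator.  When
the number of equal-size splits is small the test can enumerate all of
them exactly instead of sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "NormalityDiagnostic",
    "bootstrap_percentile_ci",
    "anderson_darling_normality",
    "permutation_test",
    "EXHAUSTIVE_LIMIT",
]

#: enumerate all splits exactly when C(n_A + n_B, n_A) is at most this
EXHAUSTIVE_LIMIT = 100_000

AVERAGES = ("mean", "unweighted", "weighted", "s_weighted")


@dataclass(frozen=True)
class NormalityDiagnostic:
    statistic: float | None
    p_value: float | None
    rejected_at_5pct: bool | None
    degenerate: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    lower: float
    upper: float
    level: float
    n_resamples: int
    average: str
    normality: NormalityDiagnostic
    seed: int | None

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float  # mean(A) - mean(B)
    p_value: float
    sided: str  # "one" | "two"
    alternative: str | None  # for one-sided: "A_less" | "A_greater"
    n_permutations: int
    n_A: int
    n_B: int
    exhaustive: bool
    seed: int | None


def _class_average(
    values: np.ndarray,
    labels: np.ndarray | None,
    similarities: dict | None,
    average: str,
) -> float:
    if average in ("mean", "weighted") or labels is None:
        return float(values.mean())
    out_means, out_weights = [], []
    for lab in np.unique(labels):
        sel = values[labels == lab]
        if average == "unweighted":
            w = 1.0
        else:
            s = similarities[lab]
            w = len(sel) ** (1.0 - s)
        out_means.append(sel.mean())
        out_weights.append(w)
    w = np.asarray(out_weights)
    return float((w * np.asarray(out_means)).sum() / w.sum())


def anderson_darling_normality(distribution: Sequence[float]) -> NormalityDiagnostic:
    """Anderson-Darling test of normality, as a diagnostic flag.

    Constant (degenerate) distributions are flagged rather than crashed on.
    """
    x = np.asarray(distribution, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 values for the normality diagnostic")
    if np.ptp(x) == 0:
        return NormalityDiagnostic(None, None, None, degenerate=True)
    stat, p = normal_ad(x)
    return NormalityDiagnostic(float(stat), float(p), bool(p < 0.05))


def bootstrap_percentile_ci(
    values: Sequence[float],
    average: str = "mean",
    labels: Sequence[str] | None = None,
    similarities: dict[str, float] | None = None,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap percentile CI of an average of per-record values.

    ``average`` is one of ``mean`` (= ``weighted``), ``unweighted`` or
    ``s_weighted``; the class-aware averages need ``labels`` per record and
    ``s_weighted`` additionally a ``similarities`` mapping.  The bounds are
    the ``(1 - level)/2`` and ``1 - (1 - level)/2`` empirical percentiles
    of the resampled averages.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if average not in AVERAGES:
        raise ValueError(f"average must be one of {AVERAGES}")
    if average in ("unweighted", "s_weighted") and labels is None:
        raise ValueError(f"{average} average needs per-record class labels")
    if average == "s_weighted" and similarities is None:
        raise ValueError("s_weighted average needs a class->similarity mapping")
    lab = np.asarray(labels) if labels is not None else None

    rng = np.random.default_rng(seed)
    n = x.size
    classes = np.unique(lab) if lab is not None else None
    s_arr = (
        np.array([similarities[c] for c in classes])
        if average == "s_weighted"
        else None
    )
    dist = np.empty(n_resamples)
    chunk = max(1, int(2e7 // n))  # bound transient allocations
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        res = x[idx]
        if average in ("mean", "weighted") or lab is None:
            dist[done : done + m] = res.mean(axis=1)
        else:
            counts = np.empty((m, classes.size))
            sums = np.empty((m, classes.size))
            lab_res = lab[idx]
            for ci, c in enumerate(classes):
                msk = lab_res == c
                counts[:, ci] = msk.sum(axis=1)
                sums[:, ci] = (res * msk).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(counts > 0, sums / counts, 0.0)
            if average == "unweighted":
                weights = (counts > 0).astype(float)
            else:
                with np.errstate(invalid="ignore"):
                    weights = np.where(counts > 0, counts ** (1.0 - s_arr[None, :]), 0.0)
            dist[done : done + m] = (weights * means).sum(axis=1) / weights.sum(axis=1)
        done += m

    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(dist, [100 * alpha, 100 * (1 - alpha)])
    point = _class_average(x, lab, similarities, average)
    return BootstrapResult(
        point_estimate=point,
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_resamples=n_resamples,
        average=average,
        normality=anderson_darling_normality(dist)
        if n_resamples >= 8
        else NormalityDiagnostic(None, None, None, degenerate=True),
        seed=seed,
    )


def _permuted_mean_diffs(
    pooled: np.ndarray, n_a: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    n = pooled.size
    out = np.empty(n_permutations)
    # chunked so huge requests do not allocate n_permutations x n at once
    chunk = max(1, int(2e7 / n))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(pooled, (m, n)).copy(), axis=1)
        out[done : done + m] = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        done += m
    return out


def _exhaustive_mean_diffs(pooled: np.ndarray, n_a: int) -> np.ndarray:
    n = pooled.size
    total = pooled.sum()
    diffs = []
    for comb in combinations(range(n), n_a):
        sa = pooled[list(comb)].sum()
        diffs.append(sa / n_a - (total - sa) / (n - n_a))
    return np.asarray(diffs)


def permutation_test(
    A: Sequence[float],
    B: Sequence[float],
    sided: str = "two",
    alternative: str | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test on the difference of means of two value sets.

    ``sided="one"`` requires ``alternative`` (``"A_less"`` or
    ``"A_greater"``); ``sided="two"`` uses the absolute difference.  With
    ``exhaustive=None`` all equal-size splits are enumerated exactly
    whenever there are at most :data:`EXHAUSTIVE_LIMIT` of them.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets must be non-empty")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if sided == "one" and alternative not in ("A_less", "A_greater"):
        raise ValueError("one-sided test needs alternative='A_less' or 'A_greater'")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_splits = math.comb(a.size + b.size, a.size)
    if exhaustive is None:
        exhaustive = n_splits <= EXHAUSTIVE_LIMIT
    if exhaustive:
        if n_splits > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{n_splits} splits exceed the exhaustive limit {EXHAUSTIVE_LIMIT}"
            )
        diffs = _exhaustive_mean_diffs(pooled, a.size)
        n_used = n_splits
    else:
        rng = np.random.default_rng(seed)
        diffs = _permuted_mean_diffs(pooled, a.size, n_permutations, rng)
        n_used = n_permutations

    tol = 1e-12  # guard ties against float noise in recomputed means
    if sided == "two":
        k = int((np.abs(diffs) >= abs(observed) - tol).sum())
    elif alternative == "A_less":
        k = int((diffs <= observed + tol).sum())
    else:
        k = int((diffs >= observed - tol).sum())
    p = (k + 1) / (n_used + 1) if plus_one else k / n_used
    return PermutationResult(
        observed_diff=observed,
        p_value=float(p),
        sided=sided,
        alternative=alternative if sided == "one" else None,
        n_permutations=n_used,
        n_A=a.size,
        n_B=b.size,
        exhaustive=bool(exhaustive),
        seed=None if exhaustive else seed,
    )
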