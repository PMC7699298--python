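"""Jonckheere-Terpstra trend statistic with permutation and exact p-values.

The Jonckheere-Terpstra (JT) statistic tests for a monotone ordering of group
locations.  For ordered groups ``g_1 < g_2 < ... < g_k`` it sums, over every
ordered pair of groups ``(a, b)`` with ``a`` before ``b``, the Mann-Whitney
count ``#{x in a, y in b : x < y} + 0.5 * #{x == y}``; ties across groups
contribute one half to each side, which makes the complement identity

    JT(order) + JT(reversed order) == number of cross-group pairs

exact.  Empirical p-values use the add-one convention ``(b + 1) / (B + 1)``
so they are never exactly zero; an exhaustive mode enumerates every
distinguishable assignment of the observed values to the group labels and is
the reference for small designs.
"""
from __future__ import annotations

import warnings
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "jt_statistic",
    "jt_null_moments",
    "jt_permutation_p",
    "exact_assignment_count",
]

_EPS = 1e-9


def _as_arrays(values, groups) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.ndim != 1 or g.ndim != 1 or v.shape != g.shape:
        raise ValueError("values and groups must be 1-d and of equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.unique(g).size < 2:
        raise ValueError("need at least two ordered groups")
    return v, g


def _comparison_matrix(v: np.ndarray) -> np.ndarray:
    """C[i, j] = (v_i < v_j) + 0.5 * (v_i == v_j)."""
    return (v[:, None] < v[None, :]) + 0.5 * (v[:, None] == v[None, :])


def _ordered_pair_indices(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) such that sample i sits in an earlier group than j."""
    return np.nonzero(g[:, None] < g[None, :])


def jt_statistic(values: Sequence[float], groups: Sequence) -> float:
    """JT statistic for ``values`` under the ordered ``groups``.

    ``groups`` must sort in the intended trend order (use integer codes,
    0 = lowest).  Raises ``ValueError`` with a single group.
    """
    v, g = _as_arrays(values, groups)
    a_idx, b_idx = _ordered_pair_indices(g)
    C = _comparison_matrix(v)
    return float(C[a_idx, b_idx].sum())


def jt_null_moments(groups: Sequence) -> tuple[float, float]:
    """Mean and variance of JT under the no-ties permutation null."""
    g = np.asarray(groups)
    n = np.array([int((g == lev).sum()) for lev in np.unique(g)])
    N = int(g.size)
    mean = (N * N - (n * n).sum()) / 4.0
    var = (N * N * (2 * N + 3) - (n * n * (2 * n + 3)).sum()) / 72.0
    return float(mean), float(var)


def exact_assignment_count(groups: Sequence) -> int:
    """Number of distinguishable assignments of samples to the group labels."""
    g = np.asarray(groups)
    from math import factorial

    total = factorial(g.size)
    for lev in np.unique(g):
        total //= factorial(int((g == lev).sum()))
    return total


def _distinct_label_arrangements(g: np.ndarray) -> Iterator[np.ndarray]:
    """Yield every distinct arrangement of the multiset of group labels."""
    levels, counts = np.unique(g, return_counts=True)
    n = g.size
    arr = np.empty(n, dtype=levels.dtype)
    counts = counts.copy()

    def rec(pos: int):
        if pos == n:
            yield arr.copy()
            return
        for i, lev in enumerate(levels):
            if counts[i] > 0:
                counts[i] -= 1
                arr[pos] = lev
                yield from rec(pos + 1)
                counts[i] += 1

    yield from rec(0)


def _perm_jt(C: np.ndarray, idx: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """JT for each row of permuted sample indices ``idx`` (n_perm x N)."""
    return C[idx[:, a_idx], idx[:, b_idx]].sum(axis=1)


def permuted_indices(
    n_samples: int,
    n_perm: int,
    rng: np.random.Generator,
    strata: Sequence | None = None,
) -> np.ndarray:
    """(n_perm x n_samples) permutations, independently within each stratum."""
    idx = np.tile(np.arange(n_samples), (n_perm, 1))
    if strata is None:
        return rng.permuted(idx, axis=1)
    s = np.asarray(strata)
    if s.shape != (n_samples,):
        raise ValueError("strata must have one label per sample")
    for lev in np.unique(s):
        block = np.nonzero(s == lev)[0]
        idx[:, block] = rng.permuted(idx[:, block], axis=1)
    return idx


def jt_permutation_p(
    values: Sequence[float],
    groups: Sequence,
    direction: str = "increasing",
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    strata: Sequence | None = None,
    exact: bool = False,
    max_exact: int = 500_000,
) -> float:
    """One-sided empirical p-value for the JT trend.

    Parameters
    ----------
    direction
        ``"increasing"`` counts permutations with JT >= observed,
        ``"decreasing"`` those with JT <= observed.
    strata
        Optional per-sample stratum labels; permutations shuffle samples only
        within a stratum (used to keep the context blocking of a design).
    exact
        Enumerate all distinguishable assignments instead of sampling; the
        p-value is then the exact fraction of assignments as or more extreme
        (the observed assignment is one of them).  Strata are not supported
        in exact mode.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    v, g = _as_arrays(values, groups)
    C = _comparison_matrix(v)
    a_idx, b_idx = _ordered_pair_indices(g)
    obs = float(C[a_idx, b_idx].sum())
    increasing = direction == "increasing"

    if exact:
        if strata is not None:
            raise ValueError("exact enumeration does not support strata")
        total = exact_assignment_count(g)
        if total > max_exact:
            raise ValueError(
                f"{total} distinguishable assignments exceed max_exact={max_exact}"
            )
        hits = 0
        for arr in _distinct_label_arrangements(g):
            mask = arr[:, None] < arr[None, :]
            jt = float((C * mask).sum())
            if (increasing and jt >= obs - _EPS) or (not increasing and jt <= obs + _EPS):
                hits += 1
        return hits / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a very coarse empirical p-value", stacklevel=2
        )
    # canonicalise sample order within (stratum, group) so the Monte-Carlo
    # p-value is bitwise invariant to sample order within groups
    s = None if strata is None else np.asarray(strata)
    key = np.lexsort((v, g) if s is None else (v, g, s))
    v, g = v[key], g[key]
    if s is not None:
        s = s[key]
    C = _comparison_matrix(v)
    a_idx, b_idx = _ordered_pair_indices(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = permuted_indices(v.size, n_perm, rng, strata=s)
    perm = _perm_jt(C, idx, a_idx, b_idx)
    if increasing:
        b = int((perm >= obs - _EPS).sum())
    else:
        b = int((perm <= obs + _EPS).sum())
    return (b + 1) / (n_perm + 1)
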