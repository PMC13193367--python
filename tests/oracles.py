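"""Independent reference implementations used only as test oracles.

Each oracle is deliberately written with a different algorithmic
strategy than the package code it checks: exact rational arithmetic
and explicit nested-loop enumeration for the Fisher test, subset
enumeration for the rank-sum distribution, point-mass summation for
the hypergeometric tail, a dense no-pruning Markov-cluster iteration,
and exhaustive search for the optimal 1-D two-cluster split.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Fisher exact, brute force with exact rationals
# ---------------------------------------------------------------------------


def _table_probability(table: list[list[int]]) -> Fraction:
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    num = Fraction(1)
    for r in rows:
        num *= math.factorial(r)
    for c in cols:
        num *= math.factorial(c)
    den = Fraction(math.factorial(n))
    for row in table:
        for cell in row:
            den *= math.factorial(cell)
    return num / den


def _all_tables(rows: list[int], cols: list[int]):
    """All non-negative integer tables with the given margins, by
    nested iteration over the first r-1 rows."""
    c = len(cols)

    def rows_for(total: int, col_caps: list[int]):
        ranges = [range(min(total, cap) + 1) for cap in col_caps]
        for cells in itertools.product(*ranges):
            if sum(cells) == total:
                yield list(cells)

    def rec(i: int, col_left: list[int]):
        if i == len(rows) - 1:
            if all(v <= rows[i] for v in col_left) and sum(col_left) == rows[i]:
                yield [list(col_left)]
            return
        for row in rows_for(rows[i], col_left):
            rest = [col_left[j] - row[j] for j in range(c)]
            for tail in rec(i + 1, rest):
                yield [row] + tail

    yield from rec(0, list(cols))


def fisher_bruteforce(counts: np.ndarray) -> float:
    """Two-sided Fisher p by exhaustive enumeration with Fractions."""
    counts = np.asarray(counts, dtype=int)
    rows = [int(r) for r in counts.sum(axis=1)]
    cols = [int(c) for c in counts.sum(axis=0)]
    p_obs = _table_probability(counts.tolist())
    cutoff = p_obs * Fraction(10_000_001, 10_000_000)  # 1 + 1e-7
    total = Fraction(0)
    for table in _all_tables(rows, cols):
        p = _table_probability(table)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by point-mass summation
# ---------------------------------------------------------------------------


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational sum."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by subset enumeration
# ---------------------------------------------------------------------------


def wilcoxon_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p (no ties) by enumerating all
    assignments of the pooled ranks to the first sample."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    nx, n = len(x), len(x) + len(y)
    all_ranks = list(range(1, n + 1))
    ws = [sum(comb) for comb in itertools.combinations(all_ranks, nx)]
    total = len(ws)
    lower = sum(w <= w_obs for w in ws) / total
    upper = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# Naive dense MCL
# ---------------------------------------------------------------------------


def naive_mcl(adjacency: np.ndarray, inflation: float = 2.0, expansion: int = 2,
              self_loop: float = 1.0, max_iter: int = 200, tol: float = 1e-8,
              ) -> list[frozenset[int]]:
    """Dense Markov clustering without pruning; returns frozensets of
    node indices.  Overlaps resolved by strongest attraction, ties to
    the cluster with the smallest minimum node index."""
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, np.diagonal(A) + self_loop)
    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        Mp = np.linalg.matrix_power(M, expansion)
        Mp = Mp ** inflation
        Mp = Mp / Mp.sum(axis=0, keepdims=True)
        if np.abs(Mp - M).max() < tol:
            M = Mp
            break
        M = Mp
    eps = 1e-7
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > eps]
    # attractor systems: transitive closure of shared flow
    parent = list(range(len(attractors)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai, a in enumerate(attractors):
        for bi, b in enumerate(attractors):
            if M[a, b] > eps or M[b, a] > eps:
                ra, rb = find(ai), find(bi)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    systems: dict[int, list[int]] = {}
    for ai, a in enumerate(attractors):
        systems.setdefault(find(ai), []).append(a)
    sys_list = sorted(systems.values(), key=min)

    clusters: list[set[int]] = [set() for _ in sys_list]
    extra: list[set[int]] = []
    for j in range(n):
        flows = [max((M[a, j] for a in sys), default=0.0) for sys in sys_list]
        best = max(flows, default=0.0)
        if best <= eps:
            extra.append({j})
            continue
        for idx, f in enumerate(flows):
            if f >= best * (1 - 1e-12):
                clusters[idx].add(j)
                break
    return [frozenset(c) for c in clusters + extra if c]


# ---------------------------------------------------------------------------
# Optimal 1-D two-cluster split by exhaustive search
# ---------------------------------------------------------------------------


def best_1d_two_split(values) -> tuple[float, frozenset[int]]:
    """Minimum within-cluster sum of squares over every contiguous
    two-way split of sorted 1-D data (the optimal 2-means partition in
    one dimension is always contiguous in sorted order, but we search
    ALL bipartitions to stay assumption-free on small inputs)."""
    values = np.asarray(list(values), dtype=float)
    n = len(values)
    best_wss, best_set = np.inf, frozenset()
    for r in range(1, n):
        for combo in itertools.combinations(range(n), r):
            a = values[list(combo)]
            b = np.delete(values, list(combo))
            wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if wss < best_wss - 1e-12:
                best_wss, best_set = wss, frozenset(combo)
    return best_wss, best_set
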