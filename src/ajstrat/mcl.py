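"""Markov Cluster Algorithm (MCL) on the sparsified correlation network.

A from-scratch implementation of flow simulation on graphs: the
column-stochastic transition matrix built from edge weights (plus a
self-loop on every node) is alternately expanded (matrix power) and
inflated (elementwise power followed by column renormalization), with
small entries pruned, until the flow stabilises.  Clusters are read off
the attractor structure of the limit matrix.  Everything is
deterministic; disconnected components are never merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .network import CorrelationNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinCluster:
    cluster_id: int
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MCLResult:
    clusters: list[ProteinCluster]
    converged: bool
    n_iterations: int

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def _normalize_columns(M: sp.csr_array) -> sp.csr_array:
    col_sums = np.asarray(M.sum(axis=0)).ravel()
    dead = col_sums <= 0
    if dead.any():
        # a fully pruned column gets its self-loop back
        M = M.tolil()
        for j in np.where(dead)[0]:
            M[j, j] = 1.0
        M = M.tocsr()
        col_sums = np.asarray(M.sum(axis=0)).ravel()
    scale = sp.dia_array((1.0 / col_sums[None, :], [0]), shape=M.shape)
    return (M @ scale).tocsr()


def mcl(
    network: CorrelationNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loop: float = 1.0,
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    use_abs: bool = True,
) -> MCLResult:
    """Cluster the network by flow simulation.

    Edge weights enter as |r| (``use_abs=False`` drops negative edges
    instead), plus ``self_loop`` on every diagonal.  Iterates
    ``M <- normalize(prune(inflate(M^expansion)))`` until
    ``max |dM| < tol`` or ``max_iter``.  Nodes attracted to several
    attractor systems are assigned to the one with the largest flow
    (ties: smallest cluster id)."""
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        return MCLResult([], True, 0)
    A = network.adjacency(use_abs=use_abs).astype(float)
    A = (A + self_loop * sp.eye_array(n, format="csr")).tocsr()
    M = _normalize_columns(A)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M_prev = M
        # expansion: matrix power
        M_exp = M
        for _ in range(expansion - 1):
            M_exp = (M_exp @ M).tocsr()
        # inflation: elementwise power, then renormalize
        M_inf = M_exp.copy()
        M_inf.data = np.power(M_inf.data, inflation)
        # prune small entries, then renormalize columns
        M_inf.data[M_inf.data < prune_below] = 0.0
        M_inf.eliminate_zeros()
        M = _normalize_columns(M_inf)
        delta = abs(M - M_prev).max() if (M - M_prev).nnz else 0.0
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    clusters = _interpret(M, nodes, eps=max(prune_below, 1e-7))
    logger.info("MCL: %d clusters after %d iterations (converged=%s)",
                len(clusters), it, converged)
    return MCLResult(clusters, converged, it)


def _interpret(M: sp.csr_array, nodes: list[str], eps: float = 1e-7) -> list[ProteinCluster]:
    """Read clusters off the limit matrix: rows with positive diagonal
    are attractors; attractors that exchange flow form one attractor
    system; every node joins the system attracting it most strongly.
    ``eps`` separates genuine limit flow (O(1/cluster size)) from
    not-yet-vanished transients when pruning is weak or disabled."""
    n = len(nodes)
    M = M.copy()
    M.data[M.data < eps] = 0.0
    M.eliminate_zeros()
    diag = M.diagonal()
    attractors = np.where(diag > 0)[0]
    if len(attractors) == 0:  # pathological; treat every node as its own
        attractors = np.arange(n)

    sub = M[np.ix_(attractors, attractors)]
    sub = sub + sub.T
    n_sys, sys_label = connected_components(sub, directed=False)

    # deterministic cluster ids: order systems by their smallest node index
    order = sorted(range(n_sys), key=lambda s: attractors[sys_label == s].min())
    sys_rank = {s: r for r, s in enumerate(order)}

    assignment = np.full(n, -1)
    attraction_csc = sp.csc_array(M[attractors, :])  # rows = attractors
    for j in range(n):
        col = attraction_csc[:, [j]].toarray().ravel()
        if col.max() <= 0:
            continue
        # strongest attraction wins; ties go to the smallest cluster id
        best = col.max()
        candidates = np.where(col >= best * (1 - 1e-12))[0]
        ids = sorted(sys_rank[sys_label[c]] for c in candidates)
        assignment[j] = ids[0]
    # nodes with no attractor flow (should not occur with self-loops)
    next_id = len(order)
    for j in np.where(assignment < 0)[0]:
        assignment[j] = next_id
        next_id += 1

    clusters: dict[int, set[str]] = {}
    for j, cid in enumerate(assignment):
        clusters.setdefault(int(cid), set()).add(nodes[j])
    out = [
        ProteinCluster(cluster_id=cid, members=frozenset(members))
        for cid, members in sorted(clusters.items())
    ]
    _assert_partition(out, nodes)
    return out


def _assert_partition(clusters: list[ProteinCluster], nodes: list[str]) -> None:
    seen: set[str] = set()
    for c in clusters:
        if not c.members:
            raise AssertionError("empty cluster emitted")
        if seen & c.members:
            raise AssertionError("clusters overlap")
        seen |= c.members
    if seen != set(nodes):
        raise AssertionError("clusters do not cover the node set")


def filter_clusters(
    clusters: list[ProteinCluster] | MCLResult, min_size: int = 10
) -> list[ProteinCluster]:
    """Keep clusters with at least ``min_size`` members (ids preserved)."""
    if isinstance(clusters, MCLResult):
        clusters = clusters.clusters
    return [c for c in clusters if len(c.members) >= min_size]
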