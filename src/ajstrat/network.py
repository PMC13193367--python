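"""Pearson correlation network construction and two-step sparsification.

The network is built from pairwise-complete Pearson correlations over
the expression matrix, then pruned in two steps: (1) drop every pair
with |r| below a floor (default 0.4); (2) each protein marks its
``top_k`` strongest surviving correlations (default 3) and an edge is
retained iff it is marked by at least one endpoint (union rule; a
mutual rule requiring both endpoints is available).  A hub can
therefore exceed degree ``top_k``: being in many partners' top lists
keeps those edges alive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Undirected weighted network over proteins.

    ``edges`` has columns protein_a, protein_b (a < b lexicographically),
    r (signed), abs_r, n_pairs (samples observed for both proteins).
    Isolated proteins stay in ``nodes`` with degree 0.
    """

    nodes: list[str]
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        e = self.edges
        if len(e):
            if (e["protein_a"] == e["protein_b"]).any():
                raise ValueError("self-edge in network")
            if (e["abs_r"] > 1 + 1e-12).any():
                raise ValueError("edge weight outside [-1, 1]")
            pairs = list(zip(e["protein_a"], e["protein_b"]))
            if len(set(pairs)) != len(pairs):
                raise ValueError("duplicate edge")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {node: 0 for node in self.nodes}
        for a, b in zip(self.edges["protein_a"], self.edges["protein_b"]):
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self, use_abs: bool = True) -> sp.csr_array:
        """Symmetric sparse adjacency over ``nodes`` (|r| weights by
        default; with ``use_abs=False`` negative edges are dropped)."""
        index = {node: i for i, node in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols, vals = [], [], []
        for a, b, r, abs_r in zip(
            self.edges["protein_a"],
            self.edges["protein_b"],
            self.edges["r"],
            self.edges["abs_r"],
        ):
            w = abs_r if use_abs else (r if r > 0 else 0.0)
            if w <= 0:
                continue
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_array((vals, (rows, cols)), shape=(n, n))

    def to_matrix(self) -> pd.DataFrame:
        """Dense signed correlation matrix of the retained edges (unit
        diagonal, NaN where no edge); useful to re-sparsify."""
        n = len(self.nodes)
        index = {node: i for i, node in enumerate(self.nodes)}
        R = np.full((n, n), np.nan)
        np.fill_diagonal(R, 1.0)
        for a, b, r in zip(self.edges["protein_a"], self.edges["protein_b"], self.edges["r"]):
            i, j = index[a], index[b]
            R[i, j] = R[j, i] = r
        return pd.DataFrame(R, index=self.nodes, columns=self.nodes)

    def write_edges(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_edges(path: str | Path, nodes: list[str] | None = None) -> CorrelationNetwork:
    edges = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    if nodes is None:
        nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    return CorrelationNetwork(nodes=nodes, edges=edges)


def pearson_matrix(
    expr: ExpressionMatrix, min_pairs: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation over proteins.

    Returns ``(R, support)``: R is proteins x proteins with unit
    diagonal and NaN where the pair has fewer than ``min_pairs``
    jointly observed samples (or a zero-variance protein over the
    complete-pairs set); support counts jointly observed samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    data = expr.data
    # proteins become columns for pandas' pairwise-complete corr
    R = data.T.corr(method="pearson", min_periods=max(min_pairs, 2))
    observed = data.notna().to_numpy().astype(np.float64)
    support = observed @ observed.T
    support_df = pd.DataFrame(
        support.astype(np.int64), index=data.index, columns=data.index
    )
    Rv = R.to_numpy()
    Rv[support < min_pairs] = np.nan
    np.fill_diagonal(Rv, 1.0)
    Rv = np.clip(Rv, -1.0, 1.0)
    R = pd.DataFrame(Rv, index=data.index, columns=data.index)
    n_undefined = int(np.isnan(Rv[np.triu_indices_from(Rv, k=1)]).sum())
    if n_undefined:
        logger.info("pearson_matrix: %d pairs undefined (low support or zero variance)",
                    n_undefined)
    asym = np.nanmax(np.abs(Rv - Rv.T)) if Rv.size else 0.0
    if asym > 1e-12:
        raise AssertionError(f"correlation matrix asymmetric by {asym}")
    return R, support_df


def sparsify(
    R: pd.DataFrame,
    support: pd.DataFrame | None = None,
    min_abs: float = 0.4,
    top_k: int = 3,
    rule: str = "union",
) -> CorrelationNetwork:
    """Two-step filter: drop |r| < ``min_abs``, then keep each node's
    ``top_k`` strongest surviving edges (ties broken by lexicographic
    partner id).  ``rule="union"`` retains an edge marked by either
    endpoint, ``"mutual"`` requires both."""
    if rule not in ("union", "mutual"):
        raise ValueError("rule must be 'union' or 'mutual'")
    nodes = [str(x) for x in R.index]
    n = len(nodes)
    A = R.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(A, np.nan)
    A[np.abs(A) < min_abs] = np.nan

    marked: set[tuple[int, int]] = set()
    survivors_per_node: list[np.ndarray] = []
    for i in range(n):
        js = np.where(~np.isnan(A[i]))[0]
        survivors_per_node.append(js)
        ranked = sorted(js, key=lambda j: (-abs(A[i, j]), nodes[j]))
        for j in ranked[:top_k]:
            marked.add((min(i, j), max(i, j)))

    if rule == "mutual":
        # an edge needs a mark from both endpoints
        counts: dict[tuple[int, int], int] = {}
        for i in range(n):
            ranked = sorted(survivors_per_node[i], key=lambda j: (-abs(A[i, j]), nodes[j]))
            for j in ranked[:top_k]:
                key = (min(i, j), max(i, j))
                counts[key] = counts.get(key, 0) + 1
        marked = {key for key, c in counts.items() if c == 2}

    rows = []
    for i, j in sorted(marked):
        a, b = nodes[i], nodes[j]
        if b < a:
            a, b = b, a
        n_pairs = int(support.loc[a, b]) if support is not None else -1
        rows.append((a, b, float(R.iloc[i, j]), abs(float(R.iloc[i, j])), n_pairs))
    edges = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "r", "abs_r", "n_pairs"]
    ).sort_values(["protein_a", "protein_b"], ignore_index=True)
    network = CorrelationNetwork(nodes=nodes, edges=edges)
    logger.info(
        "sparsify: %d nodes, %d edges retained (min_abs=%g, top_k=%d, %s rule)",
        n, network.n_edges, min_abs, top_k, rule,
    )
    return network


def build_network(
    expr: ExpressionMatrix,
    min_abs: float = 0.4,
    top_k: int = 3,
    min_pairs: int = 10,
    rule: str = "union",
) -> CorrelationNetwork:
    """Convenience: ``sparsify(pearson_matrix(expr))``."""
    R, support = pearson_matrix(expr, min_pairs=min_pairs)
    return sparsify(R, support, min_abs=min_abs, top_k=top_k, rule=rule)
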