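"""Hypergeometric overrepresentation analysis (ORA) with BH adjustment.

Used twice in the pipeline: to annotate protein clusters against a
gene-set collection (identifying the adherens-junction cluster) and to
characterise the proteins upregulated in AJ-low tumors.  The test is
the upper-tail hypergeometric probability P(X >= k) of drawing ``k``
set members in a query of size ``n`` from a universe of ``N`` proteins
of which ``K`` belong to the set; the universe is the quantified
proteome.  Benjamini-Hochberg adjustment is applied across the sets
tested within one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    universe_N: int
    set_K: int
    query_n: int
    overlap_k: int
    p: float
    adj_p: float
    overlap_ids: frozenset[str]
    tested: bool  # False when overlap < min_overlap (excluded from BH)

    def __post_init__(self) -> None:
        assert self.overlap_k <= min(self.set_K, self.query_n)
        assert 0.0 <= self.p <= 1.0


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (or Bonferroni), mapped
    back to input order and capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=sm_method)[1]


def ora(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    min_overlap: int = 2,
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Test the query against every gene set in the collection.

    Set members outside the universe are dropped (logged); sets whose
    query overlap is below ``min_overlap`` are reported with p = 1 and
    excluded from the adjustment.  Results sorted by (adj_p, set_name).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    universe = set(universe)
    dropped = len(query) - len(set(query) & universe)
    if dropped:
        logger.info("ora: dropped %d query members outside the universe", dropped)
    query = set(query) & universe
    if not query:
        raise ValueError("query has no members inside the universe")

    N, n = len(universe), len(query)
    results: list[EnrichmentResult] = []
    for name in sets.names():
        members = sets.sets[name] & universe
        K = len(members)
        overlap = query & members
        k = len(overlap)
        tested = k >= min_overlap and K > 0
        if tested:
            p = float(hypergeom.sf(k - 1, N, K, n))
            p = min(max(p, 0.0), 1.0)
        else:
            p = 1.0
        results.append(
            EnrichmentResult(
                set_name=name, universe_N=N, set_K=K, query_n=n,
                overlap_k=k, p=p, adj_p=1.0, overlap_ids=frozenset(overlap),
                tested=tested,
            )
        )
    tested_idx = [i for i, r in enumerate(results) if r.tested]
    if tested_idx:
        adj = bh_adjust([results[i].p for i in tested_idx], method=method)
        for i, a in zip(tested_idx, adj):
            results[i].adj_p = float(a)
    n_skipped = len(results) - len(tested_idx)
    if n_skipped:
        logger.info("ora: %d sets below min_overlap=%d excluded from adjustment",
                    n_skipped, min_overlap)
    results.sort(key=lambda r: (r.adj_p, r.set_name))
    return results


def results_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "universe_N": [r.universe_N for r in results],
            "set_K": [r.set_K for r in results],
            "query_n": [r.query_n for r in results],
            "overlap_k": [r.overlap_k for r in results],
            "p": [r.p for r in results],
            "adj_p": [r.adj_p for r in results],
            "tested": [r.tested for r in results],
            "overlap_ids": ["|".join(sorted(r.overlap_ids)) for r in results],
        }
    )
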