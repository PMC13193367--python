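"""Parameter-recovery evaluation on synthetic cohorts.

Runs the cluster-recovery portion of the pipeline (correlation network
-> MCL -> size filter -> ORA -> AJ-cluster selection -> K-means
stratification) on a generated cohort and scores it against the planted
ground truth: Jaccard overlap of the recovered AJ cluster with the
planted module, majority-matched stratification accuracy, and the
AJ x response Fisher p-values per therapy arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import RunConfig
from .enrichment import ora
from .mcl import filter_clusters, mcl
from .network import build_network
from .pipeline import select_aj_cluster
from .stats import build_tables
from .stratification import kmeans_split
from .synthetic import CohortConfig, GroundTruth, generate_cohort


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class RecoveryScore:
    seed: int
    aj_cluster_found: bool
    aj_jaccard: float
    accuracy: float
    fisher_p: dict[str, float]  # therapy -> AJ x response p
    n_clusters_min_size: int
    module_cluster_survived: bool  # a size-filtered cluster holds >= half the module


def evaluate_recovery(
    seed: int,
    cohort_config: CohortConfig | None = None,
    run_config: RunConfig | None = None,
) -> RecoveryScore:
    """Generate one cohort with the given seed and score recovery."""
    cohort = replace(cohort_config or CohortConfig(), seed=seed)
    run = run_config or RunConfig()
    expr, clinical, truth, gene_sets = generate_cohort(cohort)

    network = build_network(
        expr, min_abs=run.corr_min_abs, top_k=run.top_k,
        min_pairs=run.corr_min_pairs, rule=run.topk_rule,
    )
    result = mcl(
        network, inflation=run.mcl_inflation, expansion=run.mcl_expansion,
        self_loop=run.mcl_self_loop, prune_below=run.mcl_prune_below,
        max_iter=run.mcl_max_iter, tol=run.mcl_tol, use_abs=run.use_abs_weights,
    )
    clusters = filter_clusters(result, min_size=run.min_cluster_size)
    module_survived = any(
        len(c.members & truth.module_proteins) >= len(truth.module_proteins) / 2
        for c in clusters
    )

    universe = set(expr.protein_ids)
    enrichment = {
        c.cluster_id: ora(set(c.members), gene_sets, universe,
                          min_overlap=run.ora_min_overlap, method=run.adjust_method)
        for c in clusters
    }
    aj_name = gene_sets.find(run.aj_set_names)
    aj_cluster, _adj_p = select_aj_cluster(clusters, enrichment, aj_name, run.ora_adj_p)

    if aj_cluster is None:
        return RecoveryScore(
            seed=seed, aj_cluster_found=False, aj_jaccard=0.0,
            accuracy=float("nan"), fisher_p={},
            n_clusters_min_size=len(clusters),
            module_cluster_survived=module_survived,
        )

    strat = kmeans_split(
        expr.subset_proteins(aj_cluster.members),
        k=run.kmeans_k, n_restarts=run.kmeans_restarts, seed=run.seed,
    )
    fisher_p: dict[str, float] = {}
    for res in build_tables(clinical, strat, max_total=run.fisher_max_total):
        if res.name.endswith("aj_x_response"):
            fisher_p[res.name.split(":")[0]] = res.p
    return RecoveryScore(
        seed=seed, aj_cluster_found=True,
        aj_jaccard=jaccard(aj_cluster.members, truth.module_proteins),
        accuracy=strat.accuracy_against(truth.aj_label_true),
        fisher_p=fisher_p,
        n_clusters_min_size=len(clusters),
        module_cluster_survived=module_survived,
    )
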