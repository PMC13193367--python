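"""End-to-end orchestration of the network-stratification analysis.

Stages: correlation network -> MCL protein clusters (size >= 10) ->
per-cluster ORA -> adherens-junction cluster selection (the cluster
with the smallest adjusted ORA p for the configured AJ gene set, among
those significantly enriched) -> K-means patient stratification ->
per-therapy Fisher association tests -> moderated-t differential
expression -> matrisome partition -> ORA of proteins upregulated in
AJ-low -> histology/AJ distance comparisons.  When no cluster is
enriched for the AJ set the downstream AJ stages are skipped and the
result records "no AJ cluster".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import distances as dist_mod
from .config import RunConfig
from .de import EBayesPrior, fit_moderated_t, matrisome_partition
from .enrichment import EnrichmentResult, ora, results_to_frame
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_summary,
)
from .mcl import MCLResult, ProteinCluster, filter_clusters, mcl
from .network import CorrelationNetwork, pearson_matrix, sparsify
from .stats import AssociationResult, associations_to_frame, build_tables, wilcoxon_ranksum
from .stratification import (
    StratificationResult,
    kmeans_split,
    write_stratification,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class ReportBundle:
    network: CorrelationNetwork
    mcl_result: MCLResult
    clusters: list[ProteinCluster]
    cluster_enrichment: dict[int, list[EnrichmentResult]]
    aj_cluster: ProteinCluster | None
    aj_set_name: str | None
    aj_adj_p: float | None
    stratification: StratificationResult | None
    associations: list[AssociationResult]
    de_results: pd.DataFrame | None
    de_prior: EBayesPrior | None
    matrisome_counts: tuple[int, int] | None
    up_in_low_enrichment: list[EnrichmentResult] | None
    distance_summaries: list[dist_mod.DistanceSummary]
    distance_tests: list[tuple[str, float]]
    summary: dict[str, object] = field(default_factory=dict)

    def write_reports(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.network.write_edges(outdir / "edges.tsv")
        rows = [
            (pid, c.cluster_id, len(c.members))
            for c in self.mcl_result.clusters
            for pid in sorted(c.members)
        ]
        pd.DataFrame(rows, columns=["protein_id", "cluster_id", "cluster_size"]).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        enr_frames = []
        for cid, results in self.cluster_enrichment.items():
            frame = results_to_frame(results)
            frame.insert(0, "cluster_id", cid)
            enr_frames.append(frame)
        if enr_frames:
            pd.concat(enr_frames, ignore_index=True).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
        if self.stratification is not None:
            write_stratification(self.stratification, outdir / "stratification.tsv")
        if self.associations:
            associations_to_frame(self.associations).to_csv(
                outdir / "associations.tsv", sep="\t", index=False
            )
        if self.de_results is not None:
            self.de_results.to_csv(outdir / "de.tsv", sep="\t", index=False)
        if self.up_in_low_enrichment is not None:
            results_to_frame(self.up_in_low_enrichment).to_csv(
                outdir / "up_in_low_enrichment.tsv", sep="\t", index=False
            )
        if self.distance_summaries:
            frame = dist_mod.summaries_to_frame(self.distance_summaries)
            frame.to_csv(outdir / "distances.tsv", sep="\t", index=False)
        write_summary(self.summary, outdir / "summary.tsv")


def select_aj_cluster(
    clusters: list[ProteinCluster],
    cluster_enrichment: dict[int, list[EnrichmentResult]],
    aj_set_name: str,
    adj_p_max: float,
) -> tuple[ProteinCluster | None, float | None]:
    """The cluster with the smallest adjusted ORA p for the AJ set,
    among clusters significantly enriched for it."""
    best: tuple[float, int] | None = None
    for cluster in clusters:
        for res in cluster_enrichment.get(cluster.cluster_id, []):
            if res.set_name == aj_set_name and res.tested and res.adj_p < adj_p_max:
                key = (res.adj_p, cluster.cluster_id)
                if best is None or key < best:
                    best = key
    if best is None:
        return None, None
    adj_p, cid = best
    cluster = next(c for c in clusters if c.cluster_id == cid)
    return cluster, adj_p


def run_full_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    gene_sets: GeneSetCollection,
    matrisome: set[str] | None = None,
    config: RunConfig | None = None,
) -> ReportBundle:
    """Run every stage on consistent inputs; pure function of
    (inputs, config)."""
    config = config or RunConfig()
    clinical.require_samples(expr.sample_ids)
    universe = set(expr.protein_ids)

    aj_set_name = gene_sets.find(config.aj_set_names)
    if aj_set_name is None:
        raise PipelineError(
            f"gene-set collection has no adherens-junction set "
            f"(looked for {config.aj_set_names})"
        )

    # --- network and clusters -----------------------------------------
    R, support = pearson_matrix(expr, min_pairs=config.corr_min_pairs)
    network = sparsify(
        R, support, min_abs=config.corr_min_abs, top_k=config.top_k,
        rule=config.topk_rule,
    )
    mcl_result = mcl(
        network,
        inflation=config.mcl_inflation,
        expansion=config.mcl_expansion,
        self_loop=config.mcl_self_loop,
        prune_below=config.mcl_prune_below,
        max_iter=config.mcl_max_iter,
        tol=config.mcl_tol,
        use_abs=config.use_abs_weights,
    )
    clusters = filter_clusters(mcl_result, min_size=config.min_cluster_size)
    logger.info("pipeline: %d clusters of size >= %d", len(clusters),
                config.min_cluster_size)

    cluster_enrichment: dict[int, list[EnrichmentResult]] = {}
    for cluster in clusters:
        cluster_enrichment[cluster.cluster_id] = ora(
            set(cluster.members), gene_sets, universe,
            min_overlap=config.ora_min_overlap, method=config.adjust_method,
        )

    aj_cluster, aj_adj_p = select_aj_cluster(
        clusters, cluster_enrichment, aj_set_name, config.ora_adj_p
    )

    summary: dict[str, object] = {
        "n_samples": expr.shape[1],
        "n_proteins": expr.shape[0],
        "n_edges": network.n_edges,
        "n_clusters_total": len(mcl_result.clusters),
        "n_clusters_min_size": len(clusters),
        "mcl_converged": mcl_result.converged,
        "aj_set_name": aj_set_name,
    }

    if aj_cluster is None:
        logger.warning("pipeline: no cluster enriched for %s -> AJ stages skipped",
                       aj_set_name)
        summary["aj_cluster_found"] = False
        associations = build_tables(clinical, None, max_total=config.fisher_max_total)
        return ReportBundle(
            network=network, mcl_result=mcl_result, clusters=clusters,
            cluster_enrichment=cluster_enrichment, aj_cluster=None,
            aj_set_name=aj_set_name, aj_adj_p=None, stratification=None,
            associations=associations, de_results=None, de_prior=None,
            matrisome_counts=None, up_in_low_enrichment=None,
            distance_summaries=[], distance_tests=[], summary=summary,
        )

    summary["aj_cluster_found"] = True
    summary["aj_cluster_id"] = aj_cluster.cluster_id
    summary["aj_cluster_size"] = len(aj_cluster.members)
    summary["aj_cluster_adj_p"] = aj_adj_p
    summary["aj_cluster_members"] = "|".join(sorted(aj_cluster.members))

    # --- stratification -------------------------------------------------
    subset = expr.subset_proteins(aj_cluster.members)
    strat = kmeans_split(
        subset, k=config.kmeans_k, n_restarts=config.kmeans_restarts,
        seed=config.seed,
    )
    summary["n_aj_low"] = sum(1 for v in strat.labels.values() if v == "low")
    summary["n_aj_high"] = sum(1 for v in strat.labels.values() if v == "high")
    summary["n_excluded_from_stratification"] = strat.n_excluded
    summary["stratification_degenerate"] = strat.degenerate

    # --- categorical associations ---------------------------------------
    associations = build_tables(clinical, strat, max_total=config.fisher_max_total)
    for res in associations:
        if res.name.endswith("aj_x_response"):
            summary[f"fisher_{res.name}"] = res.p
            summary[f"fisher_{res.name}_n"] = res.n

    # --- differential expression ----------------------------------------
    de_results, de_prior = fit_moderated_t(
        expr, strat.labels, de_p=config.de_p, de_adj_p=config.de_adj_p,
        min_per_group=config.de_min_per_group, moderation=config.moderation,
    )
    summary["n_de_tested"] = len(de_results)
    summary["n_de_significant"] = int(de_results["significant"].sum())

    matrisome_counts = None
    if matrisome:
        n_up_low, n_up_high, _table = matrisome_partition(de_results, matrisome)
        matrisome_counts = (n_up_low, n_up_high)
        summary["matrisome_up_in_low"] = n_up_low
        summary["matrisome_up_in_high"] = n_up_high

    up_in_low = set(
        de_results.loc[
            de_results["significant"] & (de_results["log2fc"] > 0), "protein_id"
        ]
    )
    up_in_low_enrichment = None
    if len(up_in_low) >= config.ora_min_overlap:
        up_in_low_enrichment = ora(
            up_in_low, gene_sets, universe,
            min_overlap=config.ora_min_overlap, method=config.adjust_method,
        )

    # --- distance analysis ----------------------------------------------
    distance_summaries: list[dist_mod.DistanceSummary] = []
    distance_tests: list[tuple[str, float]] = []
    groups = _histology_aj_groups(clinical, strat)
    group_sizes = pd.Series(list(groups.values())).value_counts()
    wanted = ["tubular_low", "tubular_high", "diffuse", "mixed"]
    if all(group_sizes.get(g, 0) >= 2 for g in wanted):
        pairs = [
            ("tubular_low", "tubular_high"),
            ("tubular_low", "diffuse"),
            ("tubular_low", "mixed"),
            ("tubular_low", "tubular_low"),
        ]
        for subset_proteins, name in (
            (set(aj_cluster.members), "AJ_CLUSTER"),
            (None, "ALL"),
        ):
            try:
                sums = dist_mod.group_distances(
                    expr, groups, pairs, subset=subset_proteins, subset_name=name
                )
            except ValueError as exc:
                logger.warning("distance analysis skipped for %s: %s", name, exc)
                continue
            distance_summaries.extend(sums)
            by_pair = {(s.group_a, s.group_b): s for s in sums}
            comparisons = [
                ("high_vs_diffuse", ("tubular_low", "tubular_high"),
                 ("tubular_low", "diffuse")),
                ("internal_vs_high", ("tubular_low", "tubular_low"),
                 ("tubular_low", "tubular_high")),
            ]
            for label, pa, pb in comparisons:
                sa, sb = by_pair.get(pa), by_pair.get(pb)
                if sa is None or sb is None:
                    continue
                p = wilcoxon_ranksum(sa.pair_distances, sb.pair_distances)
                distance_tests.append((f"{name}:{label}", p))
                summary[f"wilcoxon_{name}_{label}"] = p
            for s in sums:
                summary[f"median_{name}_{s.group_a}_vs_{s.group_b}"] = s.median
    else:
        logger.info("distance analysis skipped: a histology/AJ subgroup has < 2 samples")

    return ReportBundle(
        network=network, mcl_result=mcl_result, clusters=clusters,
        cluster_enrichment=cluster_enrichment, aj_cluster=aj_cluster,
        aj_set_name=aj_set_name, aj_adj_p=aj_adj_p, stratification=strat,
        associations=associations, de_results=de_results, de_prior=de_prior,
        matrisome_counts=matrisome_counts,
        up_in_low_enrichment=up_in_low_enrichment,
        distance_summaries=distance_summaries, distance_tests=distance_tests,
        summary=summary,
    )


def _histology_aj_groups(
    clinical: ClinicalTable, strat: StratificationResult
) -> dict[str, str]:
    """Group labels for the distance analysis: tubular samples split by
    AJ group, diffuse and mixed kept whole."""
    groups: dict[str, str] = {}
    for sample, label in strat.labels.items():
        histology = clinical.data.loc[sample, "histology"]
        if histology == "tubular":
            groups[sample] = f"tubular_{label}"
        elif histology in ("diffuse", "mixed"):
            groups[sample] = histology
    return groups
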