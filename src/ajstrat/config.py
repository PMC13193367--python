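"""Run configuration for the network-stratification pipeline.

All tunables of the analysis live here with their default values: the
correlation sparsification thresholds (minimum |r| 0.4, three strongest
correlations per protein), the minimum cluster size of 10 proteins, the
MCL parameters, the K-means settings and the dual significance rule for
differential expression (raw p < 0.05 and BH-adjusted p < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SCHEMA_VERSION = 1

#: gene-set names (case-insensitive) recognised as the adherens-junction set
DEFAULT_AJ_SET_NAMES = ("ADHERENS_JUNCTION", "Adherens junction")


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline.

    Parameters
    ----------
    corr_min_abs:
        Minimum absolute Pearson correlation for an edge to enter the
        network (step 1 of the sparsification).
    corr_min_pairs:
        Minimum number of samples observed for both proteins for their
        correlation to be defined at all.
    top_k:
        Number of strongest absolute correlations each protein retains
        (step 2 of the sparsification).
    topk_rule:
        ``"union"`` keeps an edge marked by at least one endpoint,
        ``"mutual"`` requires both endpoints to mark it.
    min_cluster_size:
        Protein clusters smaller than this are dropped before annotation.
    mcl_*:
        Markov Cluster Algorithm parameters (inflation, expansion power,
        self-loop weight, pruning threshold, iteration cap, convergence
        tolerance).
    use_abs_weights:
        Cluster on |r| (default) instead of dropping negative edges.
    kmeans_k / kmeans_restarts:
        Number of patient groups and Lloyd restarts for stratification.
    de_p / de_adj_p:
        Dual significance rule for differential expression.
    moderation:
        Empirical-Bayes variance shrinkage on (default) or plain pooled
        two-sample t off.
    ora_adj_p / ora_min_overlap:
        Adjusted-p cutoff used to call a cluster "enriched" and the
        minimum query/set overlap entered into the BH adjustment.
    adjust_method:
        Multiple-testing adjustment, ``"bh"`` or ``"bonferroni"``.
    aj_set_names:
        Gene-set names (matched case-insensitively) identifying the
        adherens-junction pathway in the supplied collection.
    """

    corr_min_abs: float = 0.4
    corr_min_pairs: int = 10
    top_k: int = 3
    topk_rule: str = "union"
    min_cluster_size: int = 10
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_self_loop: float = 1.0
    mcl_prune_below: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-8
    use_abs_weights: bool = True
    kmeans_k: int = 2
    kmeans_restarts: int = 50
    de_p: float = 0.05
    de_adj_p: float = 0.2
    de_min_per_group: int = 3
    moderation: bool = True
    ora_adj_p: float = 0.05
    ora_min_overlap: int = 2
    adjust_method: str = "bh"
    aj_set_names: tuple[str, ...] = DEFAULT_AJ_SET_NAMES
    fisher_max_total: int = 500
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr_min_abs <= 1.0:
            raise ValueError("corr_min_abs must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.topk_rule not in ("union", "mutual"):
            raise ValueError("topk_rule must be 'union' or 'mutual'")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must exceed 1")
        if self.mcl_expansion < 2:
            raise ValueError("mcl_expansion must be >= 2")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        for name in ("de_p", "de_adj_p", "ora_adj_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.adjust_method not in ("bh", "bonferroni"):
            raise ValueError("adjust_method must be 'bh' or 'bonferroni'")
        if isinstance(self.aj_set_names, list):
            self.aj_set_names = tuple(self.aj_set_names)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["aj_set_names"] = list(self.aj_set_names)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {version} (expected {SCHEMA_VERSION})"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
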