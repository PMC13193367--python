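"""Euclidean proteome-distance comparisons between patient subgroups.

Distances between expression profiles are computed on the unscaled log2
intensities, either over the adherens-junction protein subset or over
the full quantified proteome.  Cross-group summaries use all |A| x |B|
sample pairs; internal (within-group) summaries use all C(|A|, 2)
pairs.

Missing values are handled per sample pair: the squared differences
are summed over proteins observed in both samples and rescaled by
p / m (p = proteins in the matrix, m = proteins observed in both), the
convention of standard distance routines for incomplete data.  This
keeps medians comparable across comparisons with different sample
sets.  A strict complete-case policy (drop any protein missing in any
involved sample) is available via ``missing="complete_case"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceSummary:
    group_a: str
    group_b: str
    subset_name: str
    pair_distances: np.ndarray
    n_proteins: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_distances)

    @property
    def median(self) -> float:
        return float(np.median(self.pair_distances))


def pairwise_scaled_distances(values: np.ndarray) -> np.ndarray:
    """Symmetric sample x sample Euclidean distance matrix on rows of
    ``values`` (samples x proteins, NaN = missing), summing squared
    differences over proteins observed in both samples and rescaling by
    p / m.  A pair with no shared observed protein gets NaN."""
    X = np.asarray(values, dtype=float)
    O = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    A = X0 ** 2
    m = O @ O.T
    d2 = A @ O.T + O @ A.T - 2.0 * (X0 @ X0.T)
    p = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(m > 0, d2 * (p / m), np.nan)
    d2 = np.maximum(d2, 0.0)  # numerical guard
    return np.sqrt(d2)


def group_distances(
    expr: ExpressionMatrix,
    groups: dict[str, str],
    pairs: list[tuple[str, str]],
    subset: set[str] | None = None,
    subset_name: str = "ALL",
    missing: str = "pairwise_scaled",
) -> list[DistanceSummary]:
    """Euclidean distance summaries for the requested group pairs.

    ``groups`` maps sample id to a group label; ``pairs`` lists
    (label_a, label_b) comparisons, with label_a == label_b meaning the
    internal within-group distances.  ``subset`` restricts the proteins
    (default: full proteome).
    """
    if missing not in ("pairwise_scaled", "complete_case"):
        raise ValueError("missing must be 'pairwise_scaled' or 'complete_case'")
    members: dict[str, list[str]] = {}
    for sample, label in groups.items():
        if sample in set(expr.sample_ids):
            members.setdefault(label, []).append(sample)

    data = expr.data
    if subset is not None:
        keep = [p for p in expr.protein_ids if p in set(subset)]
        if not keep:
            raise ValueError("subset leaves no proteins")
        data = data.loc[keep]

    involved: list[str] = []
    for label_a, label_b in pairs:
        for label in {label_a, label_b}:
            if label not in members or not members[label]:
                raise ValueError(f"group {label!r} is empty")
            if label_a == label_b and len(members[label]) < 2:
                raise ValueError(
                    f"group {label!r} needs >= 2 samples for internal distances"
                )
            for s in members[label]:
                if s not in involved:
                    involved.append(s)

    block = data[involved]
    if missing == "complete_case":
        block = block[block.notna().all(axis=1)]
        if block.shape[0] == 0:
            raise ValueError("no protein observed in every involved sample")
        logger.info(
            "group_distances [%s]: %d/%d proteins complete-case over %d samples",
            subset_name, block.shape[0], data.shape[0], len(involved),
        )
    n_proteins = int(block.shape[0])
    D = pairwise_scaled_distances(block.to_numpy(dtype=float).T)
    if np.isnan(D[np.triu_indices_from(D, k=1)]).any():
        raise ValueError("a sample pair shares no observed protein")
    pos = {s: i for i, s in enumerate(involved)}

    out: list[DistanceSummary] = []
    for label_a, label_b in pairs:
        ia = [pos[s] for s in members[label_a]]
        if label_a == label_b:
            d = squareform(D[np.ix_(ia, ia)], checks=False)
        else:
            ib = [pos[s] for s in members[label_b]]
            d = D[np.ix_(ia, ib)].ravel()
        out.append(
            DistanceSummary(
                group_a=label_a, group_b=label_b, subset_name=subset_name,
                pair_distances=np.asarray(d, dtype=float),
                n_proteins=n_proteins,
            )
        )
    return out


def summaries_to_frame(summaries: list[DistanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [s.group_a for s in summaries],
            "group_b": [s.group_b for s in summaries],
            "subset_name": [s.subset_name for s in summaries],
            "n_pairs": [s.n_pairs for s in summaries],
            "n_proteins": [s.n_proteins for s in summaries],
            "median": [s.median for s in summaries],
        }
    )
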