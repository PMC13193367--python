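"""Exact categorical and rank statistics.

Fisher's exact test on general r x c contingency tables (two-sided,
by summing the conditional probabilities of all tables, given both
margins, that are no more probable than the observed one, with the
customary 1 + 1e-7 tolerance factor on the comparison), the Wilcoxon
rank-sum test, and the construction of every clinicopathological
association table the pipeline reports: response vs. pathology per
therapy arm, AJ group vs. response per therapy arm, AJ group vs.
histology / ulceration / inflammation, and histology vs. response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom, mannwhitneyu

from .io import NA_TOKENS, ClinicalTable
from .stratification import StratificationResult

logger = logging.getLogger(__name__)

#: tables no more probable than p_obs * (1 + REL_ERR) are counted in the
#: two-sided tail; matches the convention of standard exact-test software
REL_ERR = 1e-7


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table needs >= 2 rows and >= 2 columns")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if self.counts.sum() == 0:
            raise ValueError("empty table")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label/shape mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_zero_margins(self) -> "ContingencyTable | None":
        """Remove all-zero rows/columns; None if < 2 levels remain."""
        counts = self.counts
        rows = counts.sum(axis=1) > 0
        cols = counts.sum(axis=0) > 0
        if rows.sum() < 2 or cols.sum() < 2:
            return None
        return ContingencyTable(
            [l for l, keep in zip(self.row_labels, rows) if keep],
            [l for l, keep in zip(self.col_labels, cols) if keep],
            counts[np.ix_(rows, cols)],
        )


def _log_table_prob(counts: np.ndarray) -> float:
    """Log conditional probability of a table given both margins."""
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def _enumerate_tail(counts: np.ndarray) -> float:
    """Two-sided exact p by recursive enumeration of all tables with the
    observed margins, in log-factorial arithmetic."""
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    r, c = counts.shape
    log_p_obs = _log_table_prob(counts)
    cutoff = log_p_obs + math.log1p(REL_ERR)
    # constant part of the log-probability
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(counts.sum() + 1)

    total = 0.0

    def fill_row(i: int, col_left: np.ndarray, acc: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row forced by the column margins
            if (col_left <= row[i]).all() and col_left.sum() == row[i]:
                logp = const + acc - gammaln(col_left + 1).sum()
                if logp <= cutoff:
                    total += math.exp(logp)
            return
        # enumerate row i cell by cell
        def fill_cell(j: int, left_in_row: int, col_left: np.ndarray, acc: float) -> None:
            if j == c - 1:
                if left_in_row <= col_left[j]:
                    new_col = col_left.copy()
                    new_col[j] -= left_in_row
                    fill_row(i + 1, new_col, acc - gammaln(left_in_row + 1))
                return
            for v in range(min(left_in_row, col_left[j]) + 1):
                new_col = col_left.copy()
                new_col[j] -= v
                fill_cell(j + 1, left_in_row - v, new_col, acc - gammaln(v + 1))

        fill_cell(0, int(row[i]), col_left, acc)

    fill_row(0, col.copy(), 0.0)
    return min(total, 1.0)


def _fisher_2x2(counts: np.ndarray) -> float:
    """Direct hypergeometric-tail formulation for 2 x 2 tables (used as
    an internal cross-check of the enumeration)."""
    a = int(counts[0, 0])
    r1 = int(counts[0].sum())
    c1 = int(counts[:, 0].sum())
    n = int(counts.sum())
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    return float(min(pmf[pmf <= p_obs * (1 + REL_ERR)].sum(), 1.0))


def fisher_exact(table: ContingencyTable, max_total: int = 500) -> float:
    """Two-sided Fisher's exact test on an r x c table.

    All-zero rows/columns are dropped first (they carry no information);
    a table degenerate after dropping returns p = 1 with a warning.
    Totals above ``max_total`` raise (use :func:`fisher_exact_mc`).
    """
    reduced = table.drop_zero_margins()
    if reduced is None:
        logger.warning("fisher_exact: degenerate table (a margin is zero); p = 1")
        return 1.0
    if reduced.total > max_total:
        raise ValueError(
            f"table total {reduced.total} exceeds max_total={max_total}; "
            "use fisher_exact_mc for a Monte Carlo p-value"
        )
    p = _enumerate_tail(reduced.counts)
    if reduced.counts.shape == (2, 2):
        p_check = _fisher_2x2(reduced.counts)
        if not math.isclose(p, p_check, rel_tol=1e-9, abs_tol=1e-12):
            raise AssertionError(
                f"2x2 cross-check failed: enumeration {p} vs hypergeometric {p_check}"
            )
    return p


def fisher_exact_mc(
    table: ContingencyTable, n_mc: int = 100_000, seed: int = 0
) -> float:
    """Monte Carlo Fisher p-value: permute one margin's labels and count
    tables no more probable than the observed one ((1 + hits)/(1 + B))."""
    reduced = table.drop_zero_margins()
    if reduced is None:
        return 1.0
    counts = reduced.counts
    rng = np.random.default_rng(seed)
    r, c = counts.shape
    row_of = np.repeat(np.arange(r), counts.sum(axis=1))
    col_of = np.repeat(np.arange(c), counts.sum(axis=0))
    log_p_obs = _log_table_prob(counts)
    cutoff = log_p_obs + math.log1p(REL_ERR)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_of)
        sim = np.zeros((r, c), dtype=np.int64)
        np.add.at(sim, (row_of, perm), 1)
        if _log_table_prob(sim) <= cutoff:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration when the pooled sample has <= 20 observations
    and no ties; otherwise the normal approximation with tie and
    continuity corrections."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 20 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method,
                     use_continuity=True).pvalue
    )


# ---------------------------------------------------------------------------
# Association table construction
# ---------------------------------------------------------------------------

_RESPONSE_VARS = ("gender", "age_class", "ypT", "ypN", "L", "V", "Pn")
_AJ_VARS = ("histology", "ulceration", "inflammation")


def crosstab(
    data: pd.DataFrame, row_var: str, col_var: str, drop_na: bool = True
) -> ContingencyTable | None:
    """Contingency table of two clinical columns; NA/unknown rows are
    excluded by default.  None when < 2 observed levels remain."""
    sub = data[[row_var, col_var]].astype(str)
    if drop_na:
        keep = ~sub[row_var].isin(NA_TOKENS) & ~sub[col_var].isin(NA_TOKENS)
        sub = sub[keep]
    if sub.empty:
        return None
    ct = pd.crosstab(sub[row_var], sub[col_var])
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        return None
    table = ContingencyTable(
        [str(i) for i in ct.index], [str(c) for c in ct.columns], ct.to_numpy()
    )
    return table.drop_zero_margins()


@dataclass
class AssociationResult:
    name: str
    table: ContingencyTable
    n: int
    p: float


def build_tables(
    clinical: ClinicalTable,
    strat: StratificationResult | None = None,
    max_total: int = 500,
    include_unknown: bool = False,
) -> list[AssociationResult]:
    """Build and test every association the pipeline reports.

    Per therapy arm: response vs. each pathology variable, and (when a
    stratification is supplied) AJ group vs. response.  Across the
    cohort: AJ group vs. histology/ulceration/inflammation, and
    histology vs. response within the FLOT arm.  Variables with fewer
    than two observed levels are skipped with a log entry.
    """
    data = clinical.data.copy()
    if strat is not None:
        data = data[data.index.isin(strat.labels)].copy()
        data["aj_group"] = [strat.labels[s] for s in data.index]
    drop_na = not include_unknown

    results: list[AssociationResult] = []

    def add(name: str, frame: pd.DataFrame, row_var: str, col_var: str) -> None:
        table = crosstab(frame, row_var, col_var, drop_na=drop_na)
        if table is None:
            logger.info("build_tables: %s skipped (< 2 observed levels)", name)
            return
        p = fisher_exact(table, max_total=max_total)
        results.append(AssociationResult(name=name, table=table, n=table.total, p=p))

    for therapy in ("FLOT", "CROSS"):
        arm = data[data["therapy"] == therapy]
        if arm.empty:
            continue
        for var in _RESPONSE_VARS:
            add(f"{therapy}:response_x_{var}", arm, var, "response")
        if strat is not None:
            add(f"{therapy}:aj_x_response", arm, "aj_group", "response")

    if strat is not None:
        for var in _AJ_VARS:
            add(f"aj_x_{var}", data, "aj_group", var)
    flot = data[data["therapy"] == "FLOT"]
    if not flot.empty:
        add("FLOT:histology_x_response", flot, "histology", "response")
    return results


def associations_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        flat = ";".join(
            f"{r}|{c}={res.table.counts[i, j]}"
            for i, r in enumerate(res.table.row_labels)
            for j, c in enumerate(res.table.col_labels)
        )
        rows.append((res.name, flat, res.n, res.p))
    return pd.DataFrame(rows, columns=["association", "table", "n", "p"])
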