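"""File formats and validated in-memory containers.

The pipeline's substrate is a proteins x samples matrix of log2
intensities with missing values, plus a clinical annotation table with
closed categorical vocabularies, a GMT gene-set collection and a
matrisome protein list.  Readers validate on load and fail loudly,
naming the offending row or column; writers produce canonical text that
their readers parse back to equal values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan"}


@dataclass
class ExpressionMatrix:
    """Proteins x samples matrix of log2 intensities (NaN = missing).

    ``data`` is indexed by protein id (rows) and sample id (columns).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate protein id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise FormatError(
                f"expression matrix needs >= 2 proteins and >= 2 samples, got {df.shape}"
            )
        all_missing = df.isna().all(axis=1)
        if all_missing.any():
            bad = df.index[all_missing][0]
            raise FormatError(f"protein {bad!r} has no observed values")
        df = df.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        self.data = df

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def subset_proteins(self, proteins: Iterable[str]) -> "ExpressionMatrix":
        keep = [p for p in self.protein_ids if p in set(proteins)]
        return ExpressionMatrix(self.data.loc[keep])


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV whose first column is the protein id and whose header
    row holds sample ids.  Empty cells (or "NA"/"NaN", case-insensitive)
    are missing values."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: expected a header row and >= 1 sample column")

    def _parse(cell: str, protein: str, sample: str) -> float:
        token = cell.strip()
        if token.lower() in _MISSING_TOKENS:
            return np.nan
        try:
            return float(token)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric value {cell!r} at protein {protein!r}, "
                f"sample {sample!r}"
            ) from None

    values = np.empty(df.shape, dtype=float)
    for j, sample in enumerate(df.columns):
        col = df.iloc[:, j]
        for i, (protein, cell) in enumerate(col.items()):
            values[i, j] = _parse(cell, str(protein), str(sample))
    parsed = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    matrix = ExpressionMatrix(parsed)
    logger.info(
        "read expression matrix %s: %d proteins x %d samples, %.1f%% missing",
        path, matrix.shape[0], matrix.shape[1], 100 * matrix.missing_fraction(),
    )
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the canonical expression TSV: 6-decimal values, empty cell
    for missing.  write -> read -> write is byte-stable."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(matrix.sample_ids) + "\n")
        values = matrix.data.to_numpy()
        for i, pid in enumerate(matrix.protein_ids):
            cells = [
                "" if np.isnan(v) else f"{v:.6f}" for v in values[i]
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

#: closed vocabularies; "NA" is the explicit missing token everywhere,
#: Pn/L/V additionally allow "unknown" as printed in the cohort tables.
CLINICAL_VOCABULARY: dict[str, tuple[str, ...]] = {
    "therapy": ("FLOT", "CROSS"),
    "response": ("major", "minor", "NA"),
    "histology": ("tubular", "diffuse", "mixed", "other", "NA"),
    "ypT": ("0", "1", "2", "3", "4", "NA"),
    "ypN": ("0", "1", "2", "3", "NA"),
    "L": ("0", "1", "unknown"),
    "V": ("0", "1", "unknown"),
    "Pn": ("0", "1", "unknown"),
    "ulceration": ("none", "few", "abundant", "NA"),
    "inflammation": ("none", "few", "abundant", "NA"),
    "gender": ("male", "female", "NA"),
    "age_class": ("lt65", "ge65", "NA"),
}

CLINICAL_COLUMNS = ("sample_id",) + tuple(CLINICAL_VOCABULARY)

#: tokens treated as "not observed" when building contingency tables
NA_TOKENS = ("NA", "unknown")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with closed vocabularies."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"clinical table missing columns: {missing_cols}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id in clinical table: {dup!r}")
        for col, vocab in CLINICAL_VOCABULARY.items():
            bad = ~df[col].astype(str).isin(vocab)
            if bad.any():
                token = df.loc[bad, col].iloc[0]
                raise FormatError(
                    f"clinical column {col!r}: unknown token {token!r} "
                    f"(allowed: {vocab})"
                )
        self.data = df[list(CLINICAL_COLUMNS)].astype(str).set_index(
            df["sample_id"].astype(str)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Every expression sample must be annotated; extras are logged."""
        wanted = list(sample_ids)
        have = set(self.data.index)
        missing = [s for s in wanted if s not in have]
        if missing:
            raise FormatError(
                f"clinical table lacks rows for samples: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = have - set(wanted)
        if extra:
            logger.info("clinical table has %d rows without expression data", len(extra))


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    table = ClinicalTable(df)
    logger.info("read clinical table %s: %d samples", path, len(table.sample_ids))
    return table


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.reset_index(drop=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, non-empty protein sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def find(self, candidates: Iterable[str]) -> str | None:
        """Return the first set whose name matches one of ``candidates``
        case-insensitively, or None."""
        lowered = {c.lower() for c in candidates}
        for name in self.sets:
            if name.lower() in lowered:
                return name
        return None


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name, description, *members = parts
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Matrisome list
# ---------------------------------------------------------------------------


def read_matrisome(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV (protein_id, category) listing extracellular
    matrix and ECM-associated proteins."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "category"):
        if col not in df.columns:
            raise FormatError(f"matrisome table missing column {col!r}")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise FormatError(f"duplicate matrisome protein: {dup!r}")
    return df


def write_matrisome(df: pd.DataFrame, path: str | Path) -> None:
    df[["protein_id", "category"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flat key-value summary
# ---------------------------------------------------------------------------


def write_summary(summary: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")


def read_summary(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            out[key] = value
    return out
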