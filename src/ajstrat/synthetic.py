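"""Synthetic cohort generator.

Emulates the statistical structure of a neoadjuvant esophageal
adenocarcinoma proteomics cohort: ~150 pre-treatment biopsies with a
planted 10-protein co-expressed adherens-junction (AJ) module, an
AJ-low patient subgroup whose module proteins are shifted down, a
therapy-specific response association (present under FLOT chemotherapy,
absent under CROSS chemoradiotherapy), histology-dependent AJ-low
frequencies, ordinal ulceration/inflammation grades linked to the AJ
group, and missing-at-random values.

Expression model, per sample ``s`` and protein ``g``::

    module protein:      X_gs = mu_g + lam * f_s - delta * 1[s is AJ-low] + eps_gs
    decoy-module protein: X_gs = mu_g + lam * h_s(module)            + eps_gs
    ECM-up protein:       X_gs = mu_g + delta * 1[s is AJ-low]       + eps_gs
    background protein:   X_gs = mu_g                                 + eps_gs

with ``f_s, h_s ~ N(0, 1)`` latent factors shared within a module,
``mu_g ~ N(20, 2)`` and ``eps ~ N(0, noise_sd^2)``.  The shared factor
makes module proteins correlate at ``r = lam^2 / (lam^2 + noise_sd^2)``
regardless of the AJ shift, so protein clustering and patient
stratification are driven by distinct parameters (``lam`` and ``delta``).

A small number of ECM-tagged background proteins receive ``+delta`` in
AJ-low samples, emulating matrisome remodeling in the AJ-low phenotype,
and a block of background proteins carries a global histology signature
(a shift in diffuse tumors, half of it in mixed tumors) so that the
subset-level and whole-proteome distance structures can disagree: at
the AJ-cluster level tubular AJ-low samples resemble diffuse tumors,
while globally they stay closer to other tubular tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_clinical,
    write_expression,
    write_gmt,
    write_matrisome,
)

logger = logging.getLogger(__name__)

HISTOLOGIES = ("tubular", "diffuse", "mixed", "other")
GRADES = ("none", "few", "abundant")


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent cohort configuration."""


def _check_probs(name: str, probs: tuple[float, ...]) -> None:
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities must sum to 1, got {sum(probs)}")


@dataclass
class CohortConfig:
    """Parameters of the generated cohort.

    ``module_loading`` (lam) is the latent-factor loading of the planted
    module proteins; ``module_shift`` (delta, log2 units) is subtracted
    from module-protein means in AJ-low samples.  Marginal frequencies
    default to the cohort the generator emulates: 45.9% FLOT, major
    response in 35%/6% of FLOT AJ-high/AJ-low patients and 26% of CROSS
    patients regardless of AJ group, AJ-low in 27%/50%/40%/33% of
    tubular/diffuse/mixed/other tumors, and inflammation/ulceration
    grade distributions shifted toward "few"/"abundant" in AJ-low.
    """

    n_samples: int = 157
    n_proteins: int = 1200
    module_size: int = 10
    module_loading: float = 1.5
    module_shift: float = 2.0
    frac_aj_low_by_histology: dict[str, float] = field(
        default_factory=lambda: {"tubular": 0.27, "diffuse": 0.50, "mixed": 0.40, "other": 0.33}
    )
    histology_mix: tuple[float, float, float, float] = (0.55, 0.18, 0.22, 0.05)
    therapy_mix: float = 0.459  # P(FLOT)
    p_major: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FLOT", "high"): 0.35,
            ("FLOT", "low"): 0.06,
            ("CROSS", "high"): 0.26,
            ("CROSS", "low"): 0.26,
        }
    )
    inflammation_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"high": (0.63, 0.28, 0.09), "low": (0.12, 0.63, 0.25)}
    )
    ulceration_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"high": (0.63, 0.30, 0.07), "low": (0.33, 0.38, 0.29)}
    )
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    n_decoy_modules: int = 5
    n_ecm_up: int = 5
    histology_signature_size: int = 150
    histology_signature_shift: float = 1.0
    matrisome_frac: float = 0.2
    n_random_sets: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_proteins:
            raise ConfigurationError("module_size cannot exceed n_proteins")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.module_loading < 0 or self.module_shift < 0:
            raise ConfigurationError("module_loading and module_shift must be >= 0")
        _check_probs("histology_mix", tuple(self.histology_mix))
        _check_probs("therapy_mix", (self.therapy_mix, 1 - self.therapy_mix))
        for group, probs in self.inflammation_probs.items():
            _check_probs(f"inflammation_probs[{group}]", tuple(probs))
        for group, probs in self.ulceration_probs.items():
            _check_probs(f"ulceration_probs[{group}]", tuple(probs))
        for key, p in {**self.frac_aj_low_by_histology, **self.p_major}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of range for {key}: {p}")
        needed = (
            (self.n_decoy_modules + 1) * self.module_size
            + self.n_ecm_up
            + self.histology_signature_size
        )
        if needed > self.n_proteins:
            raise ConfigurationError(
                f"n_proteins={self.n_proteins} too small for the planted module, "
                f"{self.n_decoy_modules} decoy modules, {self.n_ecm_up} ECM-up proteins "
                f"and a {self.histology_signature_size}-protein histology signature"
            )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["p_major"] = {f"{t}/{g}": p for (t, g), p in self.p_major.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "p_major" in data:
            data["p_major"] = {
                tuple(key.split("/")): p for key, p in data["p_major"].items()
            }
        for key in ("histology_mix",):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("inflammation_probs", "ulceration_probs"):
            if key in data:
                data[key] = {g: tuple(v) for g, v in data[key].items()}
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort (for verification only)."""

    module_proteins: frozenset[str]
    aj_label_true: dict[str, str]  # sample -> "high" | "low"
    decoy_modules: list[frozenset[str]]
    ecm_up_proteins: frozenset[str]
    histology_signature_proteins: frozenset[str]
    matrisome: pd.DataFrame  # protein_id, category


# Post-treatment pathology is drawn conditional on response, using the
# response-conditional frequencies of the cohort the generator emulates
# (pooled over both therapy arms).  These variables are plumbing for the
# clinicopathological association tables; they carry no planted link to
# the AJ group.
_PATHOLOGY_BY_RESPONSE: dict[str, dict[str, tuple[tuple[str, ...], tuple[float, ...]]]] = {
    "major": {
        "ypT": (("0", "1", "2", "3", "4"), (13 / 39, 12 / 39, 7 / 39, 7 / 39, 0.0)),
        "ypN": (("0", "1", "2", "3"), (27 / 39, 11 / 39, 1 / 39, 0.0)),
        "L": (("0", "1"), (1.0, 0.0)),
        "V": (("0", "1"), (1.0, 0.0)),
        "Pn": (("0", "1", "unknown"), (34 / 39, 0.0, 5 / 39)),
        "gender": (("male", "female"), (31 / 39, 8 / 39)),
        "age_class": (("lt65", "ge65"), (23 / 39, 16 / 39)),
    },
    "minor": {
        "ypT": (("0", "1", "2", "3", "4"), (0.0, 14 / 118, 20 / 118, 80 / 118, 4 / 118)),
        "ypN": (("0", "1", "2", "3"), (41 / 118, 31 / 118, 19 / 118, 27 / 118)),
        "L": (("0", "1"), (60 / 118, 58 / 118)),
        "V": (("0", "1", "unknown"), (88 / 118, 29 / 118, 1 / 118)),
        "Pn": (("0", "1", "unknown"), (54 / 118, 42 / 118, 22 / 118)),
        "gender": (("male", "female"), (104 / 118, 14 / 118)),
        "age_class": (("lt65", "ge65"), (77 / 118, 41 / 118)),
    },
}


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth, GeneSetCollection]:
    """Draw one cohort.  Identical config (including seed) gives
    bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_proteins
    lam, delta, sd = config.module_loading, config.module_shift, config.noise_sd

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    protein_ids = _protein_ids(p)

    # --- planted protein structure ------------------------------------
    perm = rng.permutation(p)
    cursor = 0
    module_idx = perm[cursor : cursor + config.module_size]
    cursor += config.module_size
    decoy_idx: list[np.ndarray] = []
    for _ in range(config.n_decoy_modules):
        decoy_idx.append(perm[cursor : cursor + config.module_size])
        cursor += config.module_size
    ecm_up_idx = perm[cursor : cursor + config.n_ecm_up]
    cursor += config.n_ecm_up
    signature_idx = perm[cursor : cursor + config.histology_signature_size]

    module_proteins = frozenset(protein_ids[i] for i in module_idx)
    decoy_modules = [frozenset(protein_ids[i] for i in idx) for idx in decoy_idx]
    ecm_up = frozenset(protein_ids[i] for i in ecm_up_idx)
    signature = frozenset(protein_ids[i] for i in signature_idx)

    # --- clinical structure -------------------------------------------
    histology = rng.choice(HISTOLOGIES, size=n, p=config.histology_mix)
    p_low = np.array([config.frac_aj_low_by_histology[h] for h in histology])
    aj_low = rng.random(n) < p_low
    aj_group = np.where(aj_low, "low", "high")
    therapy = np.where(rng.random(n) < config.therapy_mix, "FLOT", "CROSS")
    pm = np.array([config.p_major[(t, g)] for t, g in zip(therapy, aj_group)])
    response = np.where(rng.random(n) < pm, "major", "minor")

    def _draw_grades(probs_by_group: dict[str, tuple[float, float, float]]) -> np.ndarray:
        out = np.empty(n, dtype=object)
        for i in range(n):
            out[i] = rng.choice(GRADES, p=probs_by_group[aj_group[i]])
        return out

    inflammation = _draw_grades(config.inflammation_probs)
    ulceration = _draw_grades(config.ulceration_probs)

    clinical_rows: dict[str, list[str]] = {
        col: [] for col in ("ypT", "ypN", "L", "V", "Pn", "gender", "age_class")
    }
    for resp in response:
        dists = _PATHOLOGY_BY_RESPONSE[resp]
        for col, (levels, probs) in dists.items():
            clinical_rows[col].append(str(rng.choice(levels, p=np.asarray(probs) / sum(probs))))

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "therapy": therapy,
                "response": response,
                "histology": histology,
                "ypT": clinical_rows["ypT"],
                "ypN": clinical_rows["ypN"],
                "L": clinical_rows["L"],
                "V": clinical_rows["V"],
                "Pn": clinical_rows["Pn"],
                "ulceration": ulceration,
                "inflammation": inflammation,
                "gender": clinical_rows["gender"],
                "age_class": clinical_rows["age_class"],
            }
        )
    )

    # --- expression ----------------------------------------------------
    mu = rng.normal(20.0, 2.0, size=p)
    X = np.tile(mu[:, None], (1, n)) + rng.normal(0.0, sd, size=(p, n))

    f = rng.normal(0.0, 1.0, size=n)  # AJ-module factor
    X[module_idx, :] += lam * f[None, :]
    X[module_idx[:, None], np.where(aj_low)[0][None, :]] -= delta

    for idx in decoy_idx:
        h = rng.normal(0.0, 1.0, size=n)
        X[idx, :] += lam * h[None, :]

    X[ecm_up_idx[:, None], np.where(aj_low)[0][None, :]] += delta

    # global histology signature: shifted in diffuse, half-shifted in mixed
    if len(signature_idx) and config.histology_signature_shift > 0:
        shift = config.histology_signature_shift
        X[signature_idx[:, None], np.where(histology == "diffuse")[0][None, :]] += shift
        X[signature_idx[:, None], np.where(histology == "mixed")[0][None, :]] += shift / 2.0

    if config.missing_rate > 0:
        mask = rng.random((p, n)) < config.missing_rate
        # keep the invariant that every protein has >= 1 observed value
        full_rows = np.where(mask.all(axis=1))[0]
        for i in full_rows:
            mask[i, rng.integers(n)] = False
        X = np.where(mask, np.nan, X)

    expr = ExpressionMatrix(pd.DataFrame(X, index=protein_ids, columns=sample_ids))

    # --- gene sets ------------------------------------------------------
    non_module = sorted(set(protein_ids) - module_proteins)
    padding = rng.choice(non_module, size=5, replace=False)
    sets: dict[str, frozenset[str]] = {
        "ADHERENS_JUNCTION": frozenset(module_proteins | set(padding))
    }
    for d, decoy in enumerate(decoy_modules, 1):
        pad = rng.choice(sorted(set(protein_ids) - decoy), size=5, replace=False)
        sets[f"DECOY_MODULE_{d:02d}"] = frozenset(decoy | set(pad))
    for r in range(1, config.n_random_sets + 1):
        size = int(rng.integers(10, 41))
        members = rng.choice(protein_ids, size=size, replace=False)
        sets[f"RANDOM_SET_{r:02d}"] = frozenset(members)
    gene_sets = GeneSetCollection(sets, {name: "synthetic" for name in sets})

    # --- matrisome annotation -------------------------------------------
    n_extra = max(0, int(round(config.matrisome_frac * p)) - len(ecm_up))
    pool = sorted(set(protein_ids) - ecm_up)
    extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
    matrisome_ids = sorted(set(extra) | ecm_up)
    categories = rng.choice(["core", "associated"], size=len(matrisome_ids))
    matrisome = pd.DataFrame({"protein_id": matrisome_ids, "category": categories})

    truth = GroundTruth(
        module_proteins=module_proteins,
        aj_label_true=dict(zip(sample_ids, aj_group)),
        decoy_modules=decoy_modules,
        ecm_up_proteins=ecm_up,
        histology_signature_proteins=signature,
        matrisome=matrisome,
    )
    logger.info(
        "generated cohort: %d samples x %d proteins, %d AJ-low, %.1f%% missing",
        n, p, int(aj_low.sum()), 100 * expr.missing_fraction(),
    )
    return expr, clinical, truth, gene_sets


def write_cohort(
    outdir: str | Path,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: GroundTruth,
    gene_sets: GeneSetCollection,
) -> None:
    """Serialize a generated cohort: expression TSV, clinical CSV, GMT,
    matrisome TSV and a ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(expr, outdir / "expression.tsv")
    write_clinical(clinical, outdir / "clinical.csv")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    write_matrisome(truth.matrisome, outdir / "matrisome.tsv")
    rows = []
    for sample, label in truth.aj_label_true.items():
        rows.append(("aj_label_true", sample, label))
    for pid in sorted(truth.module_proteins):
        rows.append(("module_protein", pid, ""))
    for d, decoy in enumerate(truth.decoy_modules, 1):
        for pid in sorted(decoy):
            rows.append((f"decoy_module_{d:02d}", pid, ""))
    for pid in sorted(truth.ecm_up_proteins):
        rows.append(("ecm_up_protein", pid, ""))
    for pid in sorted(truth.histology_signature_proteins):
        rows.append(("histology_signature_protein", pid, ""))
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False
    )
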