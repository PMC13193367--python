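"""Two-group differential expression with empirical-Bayes moderated t.

For each protein the two-sample comparison (AJ-low minus AJ-high, so a
negative log2 fold change means lower expression in the AJ-low group)
uses an equal-variance pooled estimate that is shrunk toward a common
prior variance s0^2 with prior degrees of freedom d0, both estimated
from the whole ensemble of per-protein variances by moment matching on
log s^2 (the mean and variance of log s^2 are tied to digamma/trigamma
functions of the degrees of freedom; the trigamma equation is inverted
by Newton iteration).  The moderated statistic

    t_g = log2fc_g / ( s_tilde_g * sqrt(1/n_low + 1/n_high) ),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom.  A
protein is called differentially expressed by the dual rule: raw
p < 0.05 and BH-adjusted p < 0.2 (both configurable).

Missing values are handled per protein by complete cases within each
group; no imputation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .enrichment import bh_adjust
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class EBayesPrior:
    """Empirical-Bayes hyperparameters: prior degrees of freedom d0
    (0 disables shrinkage entirely; +inf shrinks every variance to
    s0_sq) and prior variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma
    (monotone and nearly linear in x)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Moment-matching fit of (d0, s0^2) to the scaled-F model of the
    per-protein sample variances ``s2`` with residual df ``df``."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        logger.info("estimate_prior: non-positive excess variance of log s^2; "
                    "d0 set to +inf (all variances shrunk to s0^2)")
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def fit_moderated_t(
    expr: ExpressionMatrix,
    labels: dict[str, str],
    de_p: float = 0.05,
    de_adj_p: float = 0.2,
    min_per_group: int = 3,
    moderation: bool = True,
    prior: EBayesPrior | None = None,
) -> tuple[pd.DataFrame, EBayesPrior | None]:
    """Moderated-t comparison of AJ-low vs AJ-high samples.

    ``labels`` maps sample id to "high"/"low"; samples absent from the
    map are ignored.  Returns a result table (one row per tested
    protein) and the fitted prior.  ``moderation=False`` (or a supplied
    ``prior`` with d0 = 0) gives the ordinary pooled two-sample t.
    """
    low = [s for s in expr.sample_ids if labels.get(s) == "low"]
    high = [s for s in expr.sample_ids if labels.get(s) == "high"]
    if not low or not high:
        raise ValueError("both groups need at least one labeled sample")

    Xl = expr.data[low].to_numpy(dtype=float)
    Xh = expr.data[high].to_numpy(dtype=float)
    nl = (~np.isnan(Xl)).sum(axis=1)
    nh = (~np.isnan(Xh)).sum(axis=1)
    usable = (nl >= min_per_group) & (nh >= min_per_group)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("fit_moderated_t: %d proteins dropped (< %d observations in a group)",
                    n_dropped, min_per_group)
    if not usable.any():
        raise ValueError("no protein has enough observations in both groups")

    idx = np.where(usable)[0]
    Xl, Xh, nl, nh = Xl[idx], Xh[idx], nl[idx], nh[idx]
    ml = np.nanmean(Xl, axis=1)
    mh = np.nanmean(Xh, axis=1)
    log2fc = ml - mh
    ssl = np.nansum((Xl - ml[:, None]) ** 2, axis=1)
    ssh = np.nansum((Xh - mh[:, None]) ** 2, axis=1)
    df_resid = nl + nh - 2.0
    s2 = (ssl + ssh) / df_resid
    s2 = np.maximum(s2, 1e-300)

    fitted_prior: EBayesPrior | None = None
    if prior is not None:
        d0, s0_sq = prior.d0, prior.s0_sq
        fitted_prior = prior
    elif moderation:
        fitted_prior = estimate_prior(s2, df_resid)
        d0, s0_sq = fitted_prior.d0, fitted_prior.s0_sq
    else:
        d0, s0_sq = 0.0, 1.0  # no shrinkage

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / nl + 1.0 / nh))
    t_mod = log2fc / se
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    adj_p = bh_adjust(p)
    significant = (p < de_p) & (adj_p < de_adj_p)

    results = pd.DataFrame(
        {
            "protein_id": [expr.protein_ids[i] for i in idx],
            "n_low": nl.astype(int),
            "n_high": nh.astype(int),
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
        }
    ).set_index("protein_id", drop=False)
    logger.info(
        "fit_moderated_t: %d/%d proteins significant (p<%g & adj_p<%g); "
        "prior d0=%.3g s0_sq=%.3g",
        int(significant.sum()), len(results), de_p, de_adj_p,
        d0 if fitted_prior else 0.0, s0_sq if fitted_prior else float("nan"),
    )
    return results, fitted_prior


def matrisome_partition(
    results: pd.DataFrame, matrisome: set[str]
) -> tuple[int, int, pd.DataFrame]:
    """Count significant matrisome proteins by direction.

    Returns ``(n_up_in_low, n_up_in_high, table)`` where up-in-low means
    significant with log2fc > 0 (low minus high convention) and the
    table lists each matrisome protein with its direction.
    """
    sub = results[results["protein_id"].isin(set(matrisome))].copy()
    direction = np.where(
        ~sub["significant"], "ns",
        np.where(sub["log2fc"] > 0, "up_in_low", "up_in_high"),
    )
    sub["direction"] = direction
    n_up_in_low = int((sub["direction"] == "up_in_low").sum())
    n_up_in_high = int((sub["direction"] == "up_in_high").sum())
    return n_up_in_low, n_up_in_high, sub
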