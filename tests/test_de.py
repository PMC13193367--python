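"""Moderated-t differential expression: no-moderation limit, prior
recovery, null calibration, planted-signal power, and agreement with
the reference empirical-Bayes implementation in R (limma)."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from ajstrat import (
    CohortConfig,
    EBayesPrior,
    estimate_prior,
    fit_moderated_t,
    generate_cohort,
    matrisome_partition,
)
from ajstrat.de import trigamma_inverse

from .conftest import make_expression


def two_group_labels(n1, n2):
    return {f"S{j:03d}": ("low" if j < n1 else "high") for j in range(n1 + n2)}


def random_expr(rng, p, n, shift_rows=0, shift=0.0, n_low=None):
    X = rng.normal(0.0, 1.0, (p, n))
    if shift_rows:
        n_low = n_low if n_low is not None else n // 2
        X[:shift_rows, :n_low] += shift
    return make_expression(X)


def test_zero_prior_df_reduces_to_ordinary_t():
    rng = np.random.default_rng(0)
    expr = random_expr(rng, 80, 30, shift_rows=10, shift=1.0, n_low=14)
    labels = two_group_labels(14, 16)
    res, _ = fit_moderated_t(expr, labels, prior=EBayesPrior(d0=0.0, s0_sq=1.0))
    X = expr.data.to_numpy()
    t_ref = ttest_ind(X[:, :14], X[:, 14:], axis=1)
    np.testing.assert_allclose(res["t_mod"], t_ref.statistic, rtol=1e-10)
    np.testing.assert_allclose(res["p"], t_ref.pvalue, rtol=1e-10)


def test_infinite_prior_df_uses_prior_variance_for_all():
    rng = np.random.default_rng(1)
    expr = random_expr(rng, 40, 20)
    res, _ = fit_moderated_t(
        expr, two_group_labels(10, 10), prior=EBayesPrior(d0=np.inf, s0_sq=2.0)
    )
    np.testing.assert_allclose(res["s2_post"], 2.0)
    assert np.isinf(res["df_total"]).all()
    se = np.sqrt(2.0 * (1 / 10 + 1 / 10))
    np.testing.assert_allclose(res["t_mod"], res["log2fc"] / se, rtol=1e-12)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for y in (1e-5, 0.01, 0.5, 2.0, 50.0, 1e6):
        x = trigamma_inverse(y)
        assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


def test_prior_recovery_from_simulated_variances():
    # s^2 ~ s0^2 * (chi2_d0/d0)^-1 * chi2_d/d with d0=4, s0^2=1
    rng = np.random.default_rng(2)
    d0_true, s0_true, d = 4.0, 1.0, 38
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
    s2 = sigma2 * rng.chisquare(d, 5000) / d
    prior = estimate_prior(s2, np.full(5000, float(d)))
    assert prior.d0 == pytest.approx(d0_true, rel=0.2)
    assert prior.s0_sq == pytest.approx(s0_true, rel=0.2)


def test_null_type_one_error_calibrated():
    fracs = []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        expr = random_expr(rng, 1000, 40)
        res, _ = fit_moderated_t(expr, two_group_labels(20, 20))
        fracs.append(float((res["p"] < 0.05).mean()))
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)


def test_planted_shift_detected_with_negative_sign():
    # module-like proteins shifted DOWN in the low group by 2 log2
    # units must come out significant with log2fc < 0 (low minus high)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(0, 1, (500, 40))
        X[:10, :20] -= 2.0
        res, _ = fit_moderated_t(make_expression(X), two_group_labels(20, 20))
        sub = res.iloc[:10]
        hits += bool(sub["significant"].all() and (sub["log2fc"] < 0).all())
    assert hits >= 9


def test_missing_values_complete_case_and_exclusion():
    rng = np.random.default_rng(3)
    X = rng.normal(0, 1, (5, 12))
    X[0, :5] = np.nan  # only 1 low observation -> excluded
    X[1, 0] = np.nan  # still >= 3 per group -> kept
    res, _ = fit_moderated_t(
        make_expression(X), two_group_labels(6, 6), min_per_group=3
    )
    assert "P000" not in res.index
    assert res.loc["P001", "n_low"] == 5


def test_significance_dual_rule():
    rng = np.random.default_rng(4)
    expr = random_expr(rng, 300, 30, shift_rows=30, shift=1.5, n_low=15)
    res, _ = fit_moderated_t(expr, two_group_labels(15, 15), de_p=0.05, de_adj_p=0.2)
    expected = (res["p"] < 0.05) & (res["adj_p"] < 0.2)
    assert (res["significant"] == expected).all()
    assert np.sign(res["t_mod"]).equals(np.sign(res["log2fc"]))


def test_matrisome_partition_counts_planted_directions():
    ok = 0
    for seed in range(10):
        config = CohortConfig(seed=200 + seed, missing_rate=0.0)
        expr, _, truth, _ = generate_cohort(config)
        res, _ = fit_moderated_t(expr, truth.aj_label_true)
        n_low, n_high, table = matrisome_partition(
            res, set(truth.matrisome["protein_id"])
        )
        planted = table[table["protein_id"].isin(truth.ecm_up_proteins)]
        ok += bool((planted["direction"] == "up_in_low").all())
        assert n_low >= len(truth.ecm_up_proteins) - 1
    assert ok >= 9


def test_matrisome_partition_empty_cases():
    rng = np.random.default_rng(5)
    res, _ = fit_moderated_t(random_expr(rng, 50, 20), two_group_labels(10, 10))
    assert matrisome_partition(res, set())[:2] == (0, 0)
    null_res = res.copy()
    null_res["significant"] = False
    assert matrisome_partition(null_res, set(res["protein_id"]))[:2] == (0, 0)


def test_matches_limma_reference(tmp_path):
    """The empirical-Bayes fit reproduces limma's eBayes to machine
    precision on a heteroskedastic two-group dataset."""
    rng = np.random.default_rng(42)
    p, n1, n2 = 60, 9, 11
    X = rng.normal(20, 1, (p, n1 + n2)) * np.sqrt(rng.chisquare(4, (p, 1)) / 4)
    X[:10, :n1] += 1.5
    expr = make_expression(X)
    res, prior = fit_moderated_t(expr, two_group_labels(n1, n2))

    x_path = tmp_path / "x.tsv"
    out_path = tmp_path / "limma.tsv"
    np.savetxt(x_path, X, delimiter="\t")
    script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.table("{x_path}", sep="\\t"))
grp <- factor(c(rep("low", {n1}), rep("high", {n2})), levels=c("high", "low"))
fit <- eBayes(lmFit(x, model.matrix(~grp)))
write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2], lfc=fit$coefficients[,2],
                       d0=fit$df.prior, s0=fit$s2.prior),
            "{out_path}", sep="\\t", quote=FALSE, row.names=FALSE)
"""
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out_path, sep="\t")
    assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
    assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-5)
    np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-8)
    np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-8)
    np.testing.assert_allclose(res["log2fc"], ref["lfc"], rtol=1e-8)
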