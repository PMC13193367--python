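"""Exact Fisher and Wilcoxon tests, and association-table construction."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ajstrat import (
    CohortConfig,
    ContingencyTable,
    build_tables,
    fisher_exact,
    fisher_exact_mc,
    generate_cohort,
    wilcoxon_ranksum,
)
from ajstrat.stratification import StratificationResult

from .oracles import fisher_bruteforce, wilcoxon_enumeration


def table(counts):
    counts = np.asarray(counts)
    r, c = counts.shape
    return ContingencyTable([f"r{i}" for i in range(r)],
                            [f"c{j}" for j in range(c)], counts)


class TestFisherExact:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact(table([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact(table([[2, 4], [3, 6]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_rational_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = int(rng.integers(2, 4))
        c = int(rng.integers(2, 4))
        counts = rng.multinomial(int(rng.integers(4, 21)),
                                 np.ones(r * c) / (r * c)).reshape(r, c)
        t = table(counts).drop_zero_margins()
        if t is None:
            return
        assert fisher_exact(t) == pytest.approx(
            fisher_bruteforce(t.counts), rel=1e-9
        )

    def test_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 15, (2, 2))
            t = table(counts).drop_zero_margins()
            if t is None:
                continue
            assert fisher_exact(t) == pytest.approx(
                scipy.stats.fisher_exact(t.counts).pvalue, rel=1e-7
            )

    def test_invariant_under_permutation_and_transpose(self):
        counts = np.array([[8, 2, 1], [3, 7, 4]])
        p = fisher_exact(table(counts))
        assert fisher_exact(table(counts[:, [2, 0, 1]])) == pytest.approx(p, rel=1e-10)
        assert fisher_exact(table(counts[[1, 0]])) == pytest.approx(p, rel=1e-10)
        assert fisher_exact(table(counts.T)) == pytest.approx(p, rel=1e-10)

    def test_zero_margin_degenerate_p_one(self):
        assert fisher_exact(table([[0, 0], [3, 4]])) == 1.0

    def test_total_above_guard_raises(self):
        with pytest.raises(ValueError, match="max_total"):
            fisher_exact(table([[300, 300], [300, 300]]))

    def test_monte_carlo_mode_converges_to_exact(self):
        counts = [[8, 3], [2, 9]]
        exact = fisher_exact(table(counts))
        n_mc, n_rep = 100_000, 3
        approx = np.mean(
            [fisher_exact_mc(table(counts), n_mc=n_mc, seed=s) for s in range(n_rep)]
        )
        se = np.sqrt(exact * (1 - exact) / (n_mc * n_rep))
        assert abs(approx - exact) <= 3 * se + 1e-4


class TestWilcoxon:
    def test_extreme_configuration_exact(self):
        # x entirely below y: p = 2 / C(4, 2)
        assert wilcoxon_ranksum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_single_tied_pair_p_one(self):
        assert wilcoxon_ranksum([5], [5]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 7))
        ny = int(rng.integers(2, 7))
        pooled = rng.choice(np.arange(100), nx + ny, replace=False).astype(float)
        x, y = pooled[:nx], pooled[nx:]
        assert wilcoxon_ranksum(x, y) == pytest.approx(
            wilcoxon_enumeration(x, y), rel=1e-10
        )

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 600
        for _ in range(n_sims):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            rejections += wilcoxon_ranksum(x, y) < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)

    def test_tied_large_samples_use_corrected_normal_approximation(self):
        # R convention: wilcox.test(x, y, correct=TRUE) with ties
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(0, 1, 15), 1)
        y = np.round(rng.normal(0.5, 1, 15), 1)
        p = wilcoxon_ranksum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


def strat_from_labels(labels):
    return StratificationResult(
        protein_subset=[], labels=labels, centroids=pd.DataFrame(),
        sample_order=list(labels), n_excluded=0,
    )


class TestBuildTables:
    def test_planted_association_flot_specific(self):
        # with the TRUE planted labels, AJ x response is associated in
        # the FLOT arm and null in the CROSS arm
        flot_p, cross_p = [], []
        for seed in range(20):
            _, clinical, truth, _ = generate_cohort(CohortConfig(seed=seed))
            results = {
                r.name: r.p
                for r in build_tables(clinical, strat_from_labels(truth.aj_label_true))
            }
            flot_p.append(results["FLOT:aj_x_response"])
            cross_p.append(results["CROSS:aj_x_response"])
        assert np.median(flot_p) < 0.05
        assert sum(p < 0.05 for p in flot_p) >= 10
        assert sum(p < 0.05 for p in cross_p) <= 3

    def test_expected_tables_present(self, default_cohort):
        _, clinical, truth, _ = default_cohort
        results = build_tables(clinical, strat_from_labels(truth.aj_label_true))
        names = {r.name for r in results}
        for want in (
            "FLOT:response_x_gender", "FLOT:response_x_ypT", "CROSS:response_x_ypN",
            "FLOT:aj_x_response", "CROSS:aj_x_response", "aj_x_histology",
            "aj_x_ulceration", "aj_x_inflammation", "FLOT:histology_x_response",
        ):
            assert want in names, want

    def test_all_response_na_skips_response_tables(self, default_cohort):
        _, clinical, truth, _ = default_cohort
        df = clinical.data.reset_index(drop=True).copy()
        df["response"] = "NA"
        from ajstrat.io import ClinicalTable

        results = build_tables(ClinicalTable(df),
                               strat_from_labels(truth.aj_label_true))
        assert all("response" not in r.name for r in results)
        assert any(r.name == "aj_x_histology" for r in results)

    def test_unknown_levels_excluded_by_default(self, default_cohort):
        _, clinical, truth, _ = default_cohort
        results = {r.name: r for r in build_tables(
            clinical, strat_from_labels(truth.aj_label_true))}
        pn = results["FLOT:response_x_Pn"]
        assert "unknown" not in pn.table.row_labels

    def test_inflammation_association_detected(self):
        hits = 0
        for seed in range(10):
            _, clinical, truth, _ = generate_cohort(CohortConfig(seed=50 + seed))
            results = {r.name: r.p for r in build_tables(
                clinical, strat_from_labels(truth.aj_label_true))}
            hits += results["aj_x_inflammation"] < 0.05
        assert hits >= 9
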