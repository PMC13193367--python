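"""Group-distance summaries on subset and full proteome."""

import numpy as np
import pytest

from ajstrat import CohortConfig, generate_cohort, group_distances
from ajstrat.distances import pairwise_scaled_distances

from .conftest import make_expression


def expr_from_samples(sample_vectors):
    return make_expression(np.asarray(sample_vectors, dtype=float).T)


class TestPairwiseDistances:
    def test_identical_samples_distance_zero(self):
        expr = expr_from_samples([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        [s] = group_distances(expr, {"S000": "a", "S001": "a"}, [("a", "a")])
        assert s.pair_distances[0] == pytest.approx(0.0)

    def test_three_four_five(self):
        # samples (1,2) and (4,6): sqrt(3^2 + 4^2) = 5
        expr = expr_from_samples([[1.0, 2.0], [4.0, 6.0]])
        [s] = group_distances(
            expr, {"S000": "a", "S001": "b"}, [("a", "b")]
        )
        assert s.pair_distances[0] == pytest.approx(5.0)

    def test_symmetry_of_cross_summaries(self):
        rng = np.random.default_rng(0)
        expr = expr_from_samples(rng.normal(0, 1, (8, 5)))
        groups = {f"S{i:03d}": ("a" if i < 4 else "b") for i in range(8)}
        [ab] = group_distances(expr, groups, [("a", "b")])
        [ba] = group_distances(expr, groups, [("b", "a")])
        assert ab.median == pytest.approx(ba.median)
        assert sorted(ab.pair_distances) == pytest.approx(sorted(ba.pair_distances))

    def test_pair_counts(self):
        rng = np.random.default_rng(1)
        expr = expr_from_samples(rng.normal(0, 1, (7, 4)))
        groups = {f"S{i:03d}": ("a" if i < 3 else "b") for i in range(7)}
        [cross, internal] = group_distances(expr, groups, [("a", "b"), ("b", "b")])
        assert cross.n_pairs == 3 * 4
        assert internal.n_pairs == 4 * 3 // 2

    def test_triangle_inequality_on_complete_data(self):
        rng = np.random.default_rng(2)
        D = pairwise_scaled_distances(rng.normal(0, 1, (10, 6)))
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_missing_rescaling_is_unbiased_in_expectation(self):
        # squared distances on masked data track the complete-data value
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (2, 400))
        full = pairwise_scaled_distances(X)[0, 1]
        Xm = X.copy()
        Xm[rng.random((2, 400)) < 0.1] = np.nan
        masked = pairwise_scaled_distances(Xm)[0, 1]
        assert masked == pytest.approx(full, rel=0.1)

    def test_no_shared_protein_is_an_error(self):
        values = np.array([[1.0, np.nan], [np.nan, 2.0]])
        expr = make_expression(values)
        with pytest.raises(ValueError, match="no observed protein|shares no"):
            group_distances(expr, {"S000": "a", "S001": "b"}, [("a", "b")])

    def test_internal_distances_need_two_samples(self):
        expr = expr_from_samples([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            group_distances(expr, {"S000": "a", "S001": "b"}, [("a", "a")])

    def test_empty_group_is_an_error(self):
        expr = expr_from_samples([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="ghost"):
            group_distances(expr, {"S000": "a", "S001": "b"}, [("a", "ghost")])

    def test_complete_case_policy_drops_incomplete_proteins(self):
        values = np.array([[1.0, 2.0], [np.nan, 3.0], [0.0, 4.0]])
        expr = make_expression(values)
        [s] = group_distances(
            expr, {"S000": "a", "S001": "b"}, [("a", "b")], missing="complete_case"
        )
        assert s.n_proteins == 2
        assert s.pair_distances[0] == pytest.approx(np.sqrt(1 + 16))


class TestSyntheticStructure:
    @staticmethod
    def _groups(clinical, truth):
        groups = {}
        for sample, label in truth.aj_label_true.items():
            hist = clinical.data.loc[sample, "histology"]
            if hist == "tubular":
                groups[sample] = f"tubular_{label}"
            elif hist in ("diffuse", "mixed"):
                groups[sample] = hist
        return groups

    def test_internal_low_group_tighter_than_cross(self, default_cohort):
        expr, clinical, truth, _ = default_cohort
        groups = self._groups(clinical, truth)
        sums = group_distances(
            expr, groups,
            [("tubular_low", "tubular_low"), ("tubular_low", "tubular_high")],
            subset=set(truth.module_proteins), subset_name="AJ",
        )
        by = {(s.group_a, s.group_b): s.median for s in sums}
        assert by[("tubular_low", "tubular_low")] < by[("tubular_low", "tubular_high")]

    def test_subset_and_global_orderings_reverse(self, default_cohort):
        # AJ-subset level: tubular AJ-low nearest the diffuse group;
        # whole-proteome level: diffuse is the farthest group
        expr, clinical, truth, _ = default_cohort
        groups = self._groups(clinical, truth)
        pairs = [("tubular_low", "tubular_high"), ("tubular_low", "diffuse")]
        aj = {(s.group_a, s.group_b): s.median for s in group_distances(
            expr, groups, pairs, subset=set(truth.module_proteins), subset_name="AJ")}
        full = {(s.group_a, s.group_b): s.median for s in group_distances(
            expr, groups, pairs)}
        assert aj[("tubular_low", "diffuse")] < aj[("tubular_low", "tubular_high")]
        assert full[("tubular_low", "diffuse")] > full[("tubular_low", "tubular_high")]

    def test_internal_vs_cross_gap_grows_with_module_shift(self):
        gaps = []
        for delta in (0.0, 1.0, 2.0, 3.0):
            config = CohortConfig(
                n_proteins=200, n_decoy_modules=0, n_ecm_up=0,
                histology_signature_size=0, module_shift=delta,
                missing_rate=0.0, seed=5,
            )
            expr, clinical, truth, _ = generate_cohort(config)
            groups = self._groups(clinical, truth)
            sums = group_distances(
                expr, groups,
                [("tubular_low", "tubular_low"), ("tubular_low", "tubular_high")],
                subset=set(truth.module_proteins), subset_name="AJ",
            )
            by = {(s.group_a, s.group_b): s.median for s in sums}
            gaps.append(by[("tubular_low", "tubular_high")]
                        - by[("tubular_low", "tubular_low")])
        assert gaps == sorted(gaps)
        assert gaps[-1] > gaps[0]
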