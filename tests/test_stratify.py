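"""Stratification: consensus clustering, Gower/PAM/silhouette, enrichment."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import comb

from ifnomics import (
    compare_scores_across_groups,
    condition_enrichment,
    consensus_cluster,
    gower_distance,
    pam_cluster,
    select_k_delta_area,
    silhouette_select_k,
)
from ifnomics.stratify import ConsensusResult, _pam_cost, _pearson_distance


def _two_cloud_panel(seed=0, n_per=15, n_markers=12):
    # centers differ per marker: correlation distance between samples is
    # blind to a uniform shift shared by every marker
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 5, size=(2, n_markers))
    X = np.vstack([centers[0] + rng.normal(0, 1, (n_per, n_markers)),
                   centers[1] + rng.normal(0, 1, (n_per, n_markers))])
    z = (X - X.mean(0)) / X.std(0)
    return pd.DataFrame(z.T, columns=[f"s{i}" for i in range(2 * n_per)])


class TestConsensus:
    def test_two_clouds_consensus_is_binary_and_exact(self):
        z = _two_cloud_panel()
        res = consensus_cluster(z, k_range=(2, 3, 4), reps=30, seed=1)
        C = res.consensus[2].to_numpy()
        assert np.isin(np.round(C, 10), [0.0, 1.0]).all()
        labels = res.labels[2].to_numpy()
        truth = np.repeat([1, 2], 15)
        same = (labels[:, None] == labels[None, :])
        assert (same == (truth[:, None] == truth[None, :])).all()

    def test_degenerate_resampling_reproduces_plain_cut(self):
        z = _two_cloud_panel(seed=2)
        res = consensus_cluster(z, k_range=(2, 3, 4), reps=1,
                                item_fraction=1.0, seed=0)
        D = _pearson_distance(z.to_numpy().T)
        for k in (2, 3, 4):
            lab = fcluster(linkage(squareform(D, checks=False), "average"),
                           t=k, criterion="maxclust")
            expected = (lab[:, None] == lab[None, :]).astype(float)
            assert np.array_equal(res.consensus[k].to_numpy(), expected)

    def test_sample_permutation_equivariance(self):
        z = _two_cloud_panel(seed=3)
        perm = np.random.default_rng(0).permutation(z.shape[1])
        res_a = consensus_cluster(z, k_range=(2, 3, 4), reps=1,
                                  item_fraction=1.0, seed=5)
        res_b = consensus_cluster(z.iloc[:, perm], k_range=(2, 3, 4), reps=1,
                                  item_fraction=1.0, seed=5)
        a = res_a.consensus[2].iloc[perm, perm].to_numpy()
        assert np.allclose(a, res_b.consensus[2].to_numpy())

    def test_consensus_matrix_contract(self):
        z = _two_cloud_panel(seed=4)
        res = consensus_cluster(z, k_range=(2, 3, 4), reps=10, seed=2)
        for C in res.consensus.values():
            M = C.to_numpy()
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert (M >= 0).all() and (M <= 1).all()

    def test_k_exceeding_n_raises(self):
        z = _two_cloud_panel(n_per=3)
        with pytest.raises(ValueError, match="exceeds"):
            consensus_cluster(z, k_range=(2, 6), reps=2)

    def test_zero_variance_marker_dropped(self):
        z = _two_cloud_panel(seed=5)
        z.loc["flat"] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            consensus_cluster(z, k_range=(2, 3, 4), reps=2, seed=0)


class TestDeltaAreaRule:
    @staticmethod
    def _result(gains):
        ks = list(range(2, 2 + len(gains)))
        return ConsensusResult(consensus={}, labels={}, auc={},
                               delta_area=dict(zip(ks, gains)))

    def test_first_subthreshold_gain_keeps_previous_k(self):
        res = self._result([0.30, 0.20, 0.02, 0.01])
        assert select_k_delta_area(res, gain_threshold=0.05) == 3

    def test_all_gains_above_threshold_warns_max_k(self):
        res = self._result([0.30, 0.20, 0.15])
        with pytest.warns(UserWarning, match="largest"):
            assert select_k_delta_area(res, gain_threshold=0.05) == 4

    def test_needs_three_k_values(self):
        with pytest.raises(ValueError, match="3"):
            select_k_delta_area(self._result([0.3, 0.2]))


class TestGower:
    def test_identical_records_distance_zero(self):
        rec = pd.DataFrame({"a": [True, True], "b": [1.0, 1.0]})
        assert gower_distance(rec).iloc[0, 1] == 0.0

    def test_all_binary_mismatch_distance_one(self):
        rec = pd.DataFrame({"a": [True, False], "b": [False, True]})
        assert gower_distance(rec).iloc[0, 1] == 1.0

    def test_three_variable_hand_computation(self):
        # equal binary (0) + differing binary (1) + numeric 5/10 -> mean 0.5
        rec = pd.DataFrame({"b1": [True, True, False],
                            "b2": [True, False, True],
                            "x": [0.0, 5.0, 10.0]})
        assert gower_distance(rec).iloc[0, 1] == pytest.approx(0.5)

    def test_missing_values_excluded_pairwise(self):
        rec = pd.DataFrame({"b1": [True, False, True],
                            "x": [np.nan, 1.0, 3.0]})
        D = gower_distance(rec)
        assert D.iloc[0, 1] == 1.0     # only b1 usable
        assert D.iloc[1, 2] == pytest.approx((1 + 2 / 2) / 2)

    def test_no_shared_variables_raises(self):
        rec = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="no non-missing"):
            gower_distance(rec)

    def test_bounds_and_symmetry_on_random_tables(self, rng):
        rec = pd.DataFrame({
            "b1": rng.random(20) > 0.5, "b2": rng.random(20) > 0.3,
            "x": rng.normal(size=20), "y": rng.uniform(0, 10, 20),
        })
        D = gower_distance(rec).to_numpy()
        assert (D >= 0).all() and (D <= 1).all()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestPam:
    @staticmethod
    def _brute_force_cost(D, k):
        n = D.shape[0]
        return min(_pam_cost(D, list(m)) for m in itertools.combinations(range(n), k))

    def test_separated_line_pairs(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        D = np.abs(pts[:, None] - pts[None, :])
        labels, medoids = pam_cluster(D, 2)
        assert labels.tolist() == [1, 1, 2, 2]

    def test_k_equals_n_costs_zero(self):
        D = np.abs(np.subtract.outer([0.0, 2, 5], [0.0, 2, 5]))
        labels, medoids = pam_cluster(D, 3)
        assert _pam_cost(D, medoids) == 0.0 and sorted(labels) == [1, 2, 3]

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2), (8, 4)])
    def test_matches_brute_force_on_small_instances(self, n, k):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 10, size=(n, 2))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            _, medoids = pam_cluster(D, k)
            assert _pam_cost(D, medoids) == pytest.approx(
                self._brute_force_cost(D, k), abs=1e-9)

    def test_invalid_inputs_raise(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="k must"):
            pam_cluster(D, 3)
        with pytest.raises(ValueError, match="symmetric"):
            pam_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        pts = np.array([0.0, 0.1, 100.0, 100.1])
        D = np.abs(pts[:, None] - pts[None, :])
        k, widths = silhouette_select_k(D, k_range=(2, 3))
        assert k == 2 and widths[2] > 0.95

    def test_hand_computed_four_point_instance(self):
        pts = np.array([0.0, 1.0, 10.0, 12.0])
        D = np.abs(pts[:, None] - pts[None, :])
        _, widths = silhouette_select_k(D, k_range=(2,))
        # direct formula: s(i) = (b - a) / max(a, b)
        a = np.array([1.0, 1.0, 2.0, 2.0])
        b = np.array([(10 + 12) / 2, (9 + 11) / 2, (10 + 9) / 2, (12 + 11) / 2])
        expected = np.mean((b - a) / np.maximum(a, b))
        assert widths[2] == pytest.approx(expected, abs=1e-12)

    def test_random_distances_give_low_widths(self, rng):
        M = rng.uniform(1, 2, size=(25, 25))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        _, widths = silhouette_select_k(D, k_range=(2, 3, 4), seed=0)
        assert max(widths.values()) < 0.25


class TestConditionEnrichment:
    @staticmethod
    def _labels(sizes):
        idx = [f"s{i}" for i in range(sum(sizes))]
        lab = np.repeat(np.arange(1, len(sizes) + 1), sizes)
        return pd.Series(lab, index=idx)

    def test_observed_expected_arithmetic(self):
        labels = self._labels([100, 100])
        flags = np.zeros(200, bool)
        flags[:10] = True          # 10 cases in cluster 1
        flags[100:130] = True      # 30 cases in cluster 2
        cond = pd.DataFrame({"cond": flags}, index=labels.index)
        _, oe = condition_enrichment(labels, cond)
        assert oe.loc["cond"].tolist() == [0.5, 1.5]

    def test_fisher_matches_hypergeometric_enumeration(self):
        labels = self._labels([10, 10])
        cond = pd.DataFrame({"cond": [True] * 10 + [False] * 10},
                            index=labels.index)
        tests, _ = condition_enrichment(labels, cond)
        expected = 2 * comb(10, 10) * comb(10, 0) / comb(20, 10)
        assert tests.loc["cond", "p"] == pytest.approx(expected, rel=1e-9)

    def test_proportional_split_is_null(self):
        labels = self._labels([100, 50])
        flags = np.zeros(150, bool)
        flags[:20] = True          # 20% of cluster 1
        flags[100:110] = True      # 20% of cluster 2
        cond = pd.DataFrame({"cond": flags}, index=labels.index)
        tests, oe = condition_enrichment(labels, cond)
        assert np.allclose(oe.loc["cond"], 1.0)
        assert tests.loc["cond", "p"] == 1.0

    def test_oe_weighted_average_is_one(self):
        labels = self._labels([80, 40, 40])
        rng = np.random.default_rng(3)
        cond = pd.DataFrame({"cond": rng.random(160) < 0.3}, index=labels.index)
        _, oe = condition_enrichment(labels, cond, n_sim=200, seed=0)
        sizes = np.array([80, 40, 40])
        assert np.average(oe.loc["cond"], weights=sizes) == pytest.approx(1.0)

    def test_min_cases_contract_enforced(self):
        labels = self._labels([20, 20])
        cond = pd.DataFrame({"rare": [True] * 3 + [False] * 37},
                            index=labels.index)
        with pytest.raises(ValueError, match="contract"):
            condition_enrichment(labels, cond)


class TestScoreComparisons:
    def test_exact_two_sided_p_for_separated_triples(self):
        scores = pd.Series([1, 2, 3, 4, 5, 6.0],
                           index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        res = compare_scores_across_groups(scores, groups)
        assert res["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        scores = pd.Series([1, 2, 3, 1, 2, 3.0],
                           index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        res = compare_scores_across_groups(scores, groups)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_power_increases_with_shift(self):
        pvals = []
        for shift in (0.0, 1.0, 3.0):
            ps = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                a = rng.normal(0, 1, 15)
                b = rng.normal(shift, 1, 15)
                s = pd.Series(np.r_[a, b], index=[f"s{i}" for i in range(30)])
                g = pd.Series(["a"] * 15 + ["b"] * 15, index=s.index)
                ps.append(compare_scores_across_groups(s, g)["p"].iloc[0])
            pvals.append(np.mean(ps))
        assert pvals[0] > pvals[1] > pvals[2]

    def test_multi_group_needs_reference_and_bh(self):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        g = pd.Series([1] * 10 + [2] * 10 + [3] * 10, index=s.index)
        with pytest.raises(ValueError, match="reference"):
            compare_scores_across_groups(s, g)
        res = compare_scores_across_groups(s, g, reference=1)
        assert len(res) == 2 and (res["q"] >= res["p"] - 1e-12).all()
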