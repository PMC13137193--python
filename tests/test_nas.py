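"""Neighborhood aggregation, NAS statistics, niche clustering, differential analysis."""

import numpy as np
import pandas as pd
import pytest

from spatialniche import (
    aggregate_neighbors,
    cluster_niches,
    differential_niche_analysis,
    nas_statistics,
    silhouette_scan,
)
from spatialniche.nas import NicheAssignment, neighborhood_matrix

from .conftest import make_net


def frame(values):
    return pd.DataFrame({"v": np.asarray(values, dtype=float)})


class TestAggregation:
    def test_isolated_node_is_its_own_neighborhood(self):
        net = make_net([(0, 0), (1, 0), (5, 5)], [(0, 1)])
        hoods = aggregate_neighbors(net, frame([1, 2, 3]))
        assert sorted(hoods[2]) == [2]

    def test_star_center_order_1(self):
        net = make_net([(0, 0), (1, 0), (0, 1), (-1, 0)], [(0, 1), (0, 2), (0, 3)])
        hoods = aggregate_neighbors(net, frame([0, 1, 2, 3]))
        assert len(hoods[0]) == 4
        assert len(hoods[1]) == 2  # leaf sees itself and the center

    def test_path_order_2(self):
        net = make_net([(0, 0), (1, 0), (2, 0)], [(0, 1), (1, 2)])
        hoods = aggregate_neighbors(net, frame([0, 1, 2]), order=2)
        assert sorted(hoods[0]) == [0, 1, 2]

    def test_exclude_self(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)])
        hoods = aggregate_neighbors(net, frame([0, 1]), include_self=False)
        assert sorted(hoods[0]) == [1]

    def test_order_zero_rejected(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)])
        with pytest.raises(ValueError, match="order"):
            aggregate_neighbors(net, frame([0, 1]), order=0)

    @pytest.mark.parametrize("order", [1, 2, 3])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bfs_oracle(self, order, seed):
        # brute-force breadth-first search on graphs of <= 12 nodes
        from .conftest import random_geometric_net

        rng = np.random.default_rng(seed)
        net = random_geometric_net(12, rng)
        adjacency = {i: set() for i in range(net.n_nodes)}
        for u, v in net.edges:
            adjacency[u].add(v)
            adjacency[v].add(u)

        def bfs(start):
            seen, frontier = {start}, {start}
            for _ in range(order):
                frontier = {w for node in frontier for w in adjacency[node]} - seen
                seen |= frontier
            return seen

        hoods = aggregate_neighbors(net, frame(np.zeros(net.n_nodes)), order=order)
        for i in range(net.n_nodes):
            assert set(hoods[i]) == bfs(i)


class TestStatistics:
    def test_hand_computed_mean_and_sd(self):
        # neighborhood values {1,0,0,0}: mean 0.25, population sd sqrt(0.1875)
        hoods = [np.array([0, 1, 2, 3])] * 4
        out = nas_statistics(frame([1, 0, 0, 0]), hoods, statistics=("mean", "sd"))
        assert out[("v", "mean")].iloc[0] == pytest.approx(0.25)
        assert out[("v", "sd")].iloc[0] == pytest.approx(np.sqrt(0.1875))

    def test_constant_neighborhood_zero_dispersion(self):
        hoods = [np.array([0, 1, 2])] * 3
        out = nas_statistics(frame([5, 5, 5]), hoods, statistics=("sd", "interdecile"))
        assert (out.to_numpy() == 0).all()

    def test_onehot_mean_is_neighborhood_proportion(self):
        onehot = pd.DataFrame({"A": [1, 1, 1, 0], "B": [0, 0, 0, 1]}, dtype=float)
        hoods = [np.array([0, 1, 2, 3])] * 4
        out = nas_statistics(onehot, hoods, statistics=("mean",))
        assert out[("A", "mean")].iloc[0] == pytest.approx(0.75)

    def test_median_and_interdecile_conventions(self):
        values = frame([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        hoods = [np.arange(10)] * 10
        out = nas_statistics(values, hoods, statistics=("median", "interdecile"))
        assert out[("v", "median")].iloc[0] == pytest.approx(5.5)
        # q90 - q10 with linear interpolation
        expected = np.quantile(np.arange(1, 11), 0.9) - np.quantile(np.arange(1, 11), 0.1)
        assert out[("v", "interdecile")].iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize("stats", [("mean",), ("mean", "sd"),
                                       ("mean", "median", "sd", "interdecile")])
    def test_column_count_is_nv_times_ns(self, stats):
        rng = np.random.default_rng(0)
        variables = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        hoods = [np.arange(6)] * 6
        out = nas_statistics(variables, hoods, statistics=stats)
        assert out.shape[1] == 3 * len(stats)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            nas_statistics(frame([1]), [np.array([0])], statistics=("mode",))


def two_sample_nas(seed=0, n=60, shift=0.0):
    """NAS-like table for two samples of two well-separated groups."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in ("S0", "S1"):
        a = rng.normal(0, 1, size=(n, 2))
        b = rng.normal(6 + shift, 1, size=(n, 2))
        block = np.vstack([a, b])
        idx = pd.MultiIndex.from_product([[sid], range(len(block))], names=["sample", "node"])
        rows.append(pd.DataFrame(block, index=idx, columns=["f0", "f1"]))
    return pd.concat(rows)


class TestClustering:
    def test_k_equal_one_single_niche(self):
        nas = two_sample_nas()
        out = cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=1, seed=0)
        assert out.n_niches == 1
        assert (out.proportions.to_numpy() == 1.0).all()

    def test_k_larger_than_cells_rejected(self):
        nas = two_sample_nas(n=3)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=1000, seed=0)

    def test_two_separated_groups_recovered(self):
        nas = two_sample_nas()
        out = cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=2, seed=0)
        labels = out.labels.to_numpy()
        # first n rows per sample are group a, rest group b
        per_sample = labels.reshape(2, -1)
        for row in per_sample:
            first, second = row[:60], row[60:]
            assert len(set(first)) == 1 and len(set(second)) == 1
            assert first[0] != second[0]

    def test_duplicated_samples_leave_labels_consistent(self):
        nas = two_sample_nas()
        out = cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=2, seed=0)
        s0 = out.labels.xs("S0", level="sample").to_numpy()
        s1 = out.labels.xs("S1", level="sample").to_numpy()
        # S1 duplicates S0's structure, so the niche proportions agree
        p = out.proportions.to_numpy()
        np.testing.assert_allclose(p[0], p[1], atol=0.05)
        assert len(s0) == len(s1)

    def test_row_order_equivariance(self):
        # permuting input rows permutes labels identically (same seed)
        nas = two_sample_nas()
        out1 = cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=2, seed=3)
        perm = np.random.default_rng(5).permutation(len(nas))
        shuffled = nas.iloc[perm].sort_index()
        out2 = cluster_niches(shuffled, dr="none", cluster="kmeans", k_or_resolution=2, seed=3)
        joined = pd.concat([out1.labels.rename("a"), out2.labels.rename("b")], axis=1)
        table = pd.crosstab(joined["a"], joined["b"]).to_numpy()
        assert (np.count_nonzero(table, axis=1) == 1).all()  # one-to-one label map

    def test_gmm_and_leiden_run(self):
        nas = two_sample_nas(n=20)
        gmm = cluster_niches(nas, dr="pca", dr_dims=2, cluster="gmm", k_or_resolution=2, seed=0)
        assert gmm.n_niches == 2
        leiden = cluster_niches(nas, dr="none", cluster="leiden", k_or_resolution=0.1, seed=0)
        assert leiden.n_niches >= 1

    def test_proportions_sum_to_one(self):
        nas = two_sample_nas()
        out = cluster_niches(nas, dr="none", cluster="kmeans", k_or_resolution=3, seed=1)
        np.testing.assert_allclose(out.proportions.sum(axis=1), 1.0)


class TestSilhouette:
    def test_two_blobs_peak_at_k2(self):
        nas = two_sample_nas()
        scan = silhouette_scan(nas, k_range=range(2, 7), seed=0)
        best_k = scan.loc[scan["silhouette"].idxmax(), "k"]
        assert best_k == 2

    def test_single_gaussian_low_silhouette(self):
        rng = np.random.default_rng(0)
        idx = pd.MultiIndex.from_product([["S0"], range(300)], names=["sample", "node"])
        nas = pd.DataFrame(rng.normal(size=(300, 2)), index=idx, columns=["f0", "f1"])
        scan = silhouette_scan(nas, k_range=[2], seed=0)
        assert scan["silhouette"].iloc[0] < 0.4

    def test_deterministic_given_seed(self):
        nas = two_sample_nas()
        s1 = silhouette_scan(nas, k_range=range(2, 5), seed=9)
        s2 = silhouette_scan(nas, k_range=range(2, 5), seed=9)
        pd.testing.assert_frame_equal(s1, s2)


class TestDifferential:
    @staticmethod
    def assignment_for(nas, labels):
        labels = pd.Series(labels, index=nas.index, name="niche")
        samples = nas.index.get_level_values("sample")
        counts = pd.crosstab(samples, labels)
        return NicheAssignment(
            labels=labels, n_niches=labels.nunique(),
            proportions=counts.div(counts.sum(axis=1), axis=0), method={},
        )

    def test_self_comparison_is_null(self):
        nas = two_sample_nas()
        niches = self.assignment_for(nas, np.zeros(len(nas), dtype=int))
        out = differential_niche_analysis(nas, niches, 0, 0)
        assert (out["q"] == 1.0).all()
        assert (out["effect"] == 0.0).all()

    def test_planted_shift_ranks_first(self):
        rng = np.random.default_rng(1)
        idx = pd.MultiIndex.from_product([["S0"], range(400)], names=["sample", "node"])
        nas = pd.DataFrame(rng.normal(size=(400, 5)),
                           columns=[f"f{i}" for i in range(5)], index=idx)
        labels = np.repeat([0, 1], 200)
        nas.loc[labels == 1, "f2"] += 3.0  # 3 SD shift in one variable
        niches = self.assignment_for(nas, labels)
        out = differential_niche_analysis(nas, niches, 1, 0)
        assert out.iloc[0]["variable"] == "f2"
        assert out.iloc[0]["q"] < 0.01
        assert out.iloc[0]["effect"] > 0

    def test_bh_adjustment_hand_case(self):
        # BH on p = (0.01, 0.02, 0.03, 0.04) with m=4 gives all q = 0.04
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)

    def test_empty_niche_after_filter_rejected(self):
        nas = two_sample_nas()
        labels = np.repeat([0, 1], len(nas) // 2)
        niches = self.assignment_for(nas, labels)
        keep = pd.Series(
            np.r_[np.ones(len(nas) // 2, dtype=bool), np.zeros(len(nas) // 2, dtype=bool)],
            index=nas.index,
        )
        with pytest.raises(ValueError, match="empty after|is empty"):
            differential_niche_analysis(nas, niches, 0, 1, cell_filter=keep)


def test_neighborhood_matrix_respects_direction_agnostic_aggregation():
    net = make_net([(0, 0), (1, 0)], [(0, 1)], directed=True)
    member = neighborhood_matrix(net, order=1)
    assert member[0, 1] and member[1, 0]  # aggregation ignores edge direction
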