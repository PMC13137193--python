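"""Mixing matrices, assortativity, permutation z-scores, imputation."""

import numpy as np
import pandas as pd
import pytest

from spatialniche import (
    MixingMatrix,
    assortativity,
    impute_missing_mm,
    mixing_matrix,
    mixing_matrix_directed,
    mixing_matrix_nonexclusive,
    zscore_mixing,
)

from .conftest import make_net, random_geometric_net


def brute_force_mm(edges, labels, directed=False):
    """Independent stub-counting oracle: loop over every edge."""
    cats = sorted(set(labels))
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)))
    for u, v in edges:
        counts[index[labels[u]], index[labels[v]]] += 1
        if not directed:
            counts[index[labels[v]], index[labels[u]]] += 1
    return counts / counts.sum(), cats


class TestMixingMatrix:
    def test_single_edge_path(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)], types="AB")
        mm = mixing_matrix(net, "cell_type")
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(mm.e, expected)
        np.testing.assert_allclose(mm.a, mm.b)

    def test_monochromatic_graph(self, triangle_net):
        mm = mixing_matrix(triangle_net, "cell_type")
        assert mm.e == pytest.approx(np.array([[1.0]]))

    def test_two_disjoint_monochromatic_triangles(self, two_triangles_net):
        mm = mixing_matrix(two_triangles_net, "cell_type")
        np.testing.assert_allclose(mm.e, np.diag([0.5, 0.5]))

    def test_empty_network_rejected(self):
        net = make_net([(0, 0), (1, 0)], np.empty((0, 2), dtype=int), types="AB")
        with pytest.raises(ValueError, match="empty network"):
            mixing_matrix(net, "cell_type")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_geometric_net(12, rng)
        mm = mixing_matrix(net, "cell_type")
        expected, cats = brute_force_mm(net.edges, list(net.attrs["cell_type"]))
        assert mm.labels == cats
        np.testing.assert_allclose(mm.e, expected)

    def test_matches_networkx(self):
        # independent library oracle for the undirected exclusive case
        import networkx as nx

        rng = np.random.default_rng(123)
        net = random_geometric_net(40, rng)
        g = nx.Graph()
        labels = list(net.attrs["cell_type"])
        g.add_nodes_from((i, {"t": labels[i]}) for i in range(net.n_nodes))
        g.add_edges_from(map(tuple, net.edges))
        mm = mixing_matrix(net, "cell_type")
        expected = nx.attribute_mixing_matrix(g, "t", mapping={c: i for i, c in enumerate(mm.labels)})
        np.testing.assert_allclose(mm.e, expected)
        assert assortativity(mm) == pytest.approx(
            nx.attribute_assortativity_coefficient(g, "t")
        )

    def test_conservation_and_marginals(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            net = random_geometric_net(30, rng)
            mm = mixing_matrix(net, "cell_type")
            assert mm.e.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(mm.e.sum(axis=1), mm.a, atol=1e-12)
            np.testing.assert_allclose(mm.e.sum(axis=0), mm.b, atol=1e-12)
            np.testing.assert_allclose(mm.e, mm.e.T, atol=1e-12)

    def test_node_relabelling_invariance(self):
        rng = np.random.default_rng(21)
        net = random_geometric_net(25, rng)
        mm1 = mixing_matrix(net, "cell_type")
        perm = rng.permutation(net.n_nodes)
        inv = np.argsort(perm)
        relabelled = make_net(
            net.coords[perm], inv[net.edges], types=net.attrs["cell_type"].to_numpy()[perm]
        )
        mm2 = mixing_matrix(relabelled, "cell_type")
        np.testing.assert_allclose(mm1.e, mm2.e)
        assert assortativity(mm1) == pytest.approx(assortativity(mm2))


class TestAssortativity:
    def test_perfectly_assortative(self, two_triangles_net):
        assert assortativity(mixing_matrix(two_triangles_net, "cell_type")) == pytest.approx(1.0)

    def test_product_marginals_give_zero(self):
        mm = MixingMatrix(e=np.full((2, 2), 0.25), labels=["A", "B"], n_edges_counted=4)
        assert assortativity(mm) == pytest.approx(0.0)

    def test_complete_bipartite_is_minus_one(self, k33_net):
        mm = mixing_matrix(k33_net, "cell_type")
        np.testing.assert_allclose(mm.e, [[0, 0.5], [0.5, 0]])
        assert assortativity(mm) == pytest.approx(-1.0)

    def test_single_category_undefined(self, triangle_net):
        mm = mixing_matrix(triangle_net, "cell_type")
        with pytest.raises(ValueError, match="undefined"):
            assortativity(mm)

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            net = random_geometric_net(30, rng)
            mm = mixing_matrix(net, "cell_type")
            if len(mm.labels) > 1:
                assert -1.0 <= assortativity(mm) <= 1.0


class TestDirected:
    def test_single_directed_edge(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)], types="AB", directed=True)
        mm = mixing_matrix_directed(net, "cell_type")
        np.testing.assert_allclose(mm.e, [[0, 1], [0, 0]])
        assert mm.a @ mm.b == pytest.approx(0.0)

    def test_two_cycle_disassortative(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1), (1, 0)], types="AB", directed=True)
        mm = mixing_matrix_directed(net, "cell_type")
        np.testing.assert_allclose(mm.e, [[0, 0.5], [0.5, 0]])
        assert assortativity(mm) == pytest.approx(-1.0)

    def test_self_preferential_edges(self):
        net = make_net(
            [(0, 0), (1, 0), (2, 0), (3, 0)],
            [(0, 1), (2, 3)],
            types="AABB",
            directed=True,
        )
        mm = mixing_matrix_directed(net, "cell_type")
        assert assortativity(mm) == pytest.approx(1.0)

    def test_undirected_input_rejected(self, triangle_net):
        with pytest.raises(ValueError, match="undirected"):
            mixing_matrix_directed(triangle_net, "cell_type")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 50)
        base = random_geometric_net(10, rng)
        directed = make_net(
            base.coords, base.edges, types=base.attrs["cell_type"], directed=True
        )
        mm = mixing_matrix_directed(directed, "cell_type")
        expected, cats = brute_force_mm(
            directed.edges, list(directed.attrs["cell_type"]), directed=True
        )
        np.testing.assert_allclose(mm.e, expected)


class TestNonExclusive:
    def test_single_shared_marker(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)], M1=[1, 1])
        mm = mixing_matrix_nonexclusive(net, ["M1"])
        assert mm.e == pytest.approx(np.array([[1.0]]))

    def test_multipositive_ordered_pairs(self):
        # u positive {M1, M2}, v positive {M1}: ordered pairs
        # (M1,M1) twice (both orientations), (M2,M1) and (M1,M2) once each
        net = make_net([(0, 0), (1, 0)], [(0, 1)], M1=[1, 1], M2=[1, 0])
        mm = mixing_matrix_nonexclusive(net, ["M1", "M2"])
        np.testing.assert_allclose(mm.e, np.array([[2, 1], [1, 0]]) / 4.0)

    def test_all_zero_flags_error(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)], M1=[0, 0])
        with pytest.raises(ValueError, match="no positive"):
            mixing_matrix_nonexclusive(net, ["M1"])

    def test_non_binary_flag_rejected(self):
        net = make_net([(0, 0), (1, 0)], [(0, 1)], M1=[2, 1])
        with pytest.raises(ValueError, match="not binary"):
            mixing_matrix_nonexclusive(net, ["M1"])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 80)
        base = random_geometric_net(12, rng)
        flags = pd.DataFrame(
            rng.integers(0, 2, size=(12, 3)), columns=["M1", "M2", "M3"]
        )
        net = make_net(base.coords, base.edges, **{c: flags[c] for c in flags})
        mm = mixing_matrix_nonexclusive(net, ["M1", "M2", "M3"])
        # brute force: one count per ordered positive pair, both orientations
        F = flags.to_numpy()
        counts = np.zeros((3, 3))
        for u, v in net.edges:
            for i in range(3):
                for j in range(3):
                    counts[i, j] += F[u, i] * F[v, j] + F[v, i] * F[u, j]
        np.testing.assert_allclose(mm.e, counts / counts.sum())
        assert mm.e.sum() == pytest.approx(1.0)


class TestZScores:
    def test_monochromatic_all_undefined(self, triangle_net):
        zs = zscore_mixing(triangle_net, "cell_type", n_perm=10, seed=0)
        assert zs.undefined_mask.all()
        assert zs.z_ac_undefined

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(31)
        net = random_geometric_net(60, rng)
        z1 = zscore_mixing(net, "cell_type", n_perm=20, seed=7)
        z2 = zscore_mixing(net, "cell_type", n_perm=20, seed=7)
        np.testing.assert_array_equal(z1.z_mm, z2.z_mm)
        assert z1.z_ac == z2.z_ac

    def test_nonexclusive_mode(self):
        rng = np.random.default_rng(41)
        base = random_geometric_net(40, rng)
        flags = pd.DataFrame(rng.integers(0, 2, size=(40, 2)), columns=["M1", "M2"])
        net = make_net(base.coords, base.edges, M1=flags["M1"], M2=flags["M2"])
        zs = zscore_mixing(net, nonexclusive=True, marker_flags=["M1", "M2"],
                           n_perm=20, seed=0)
        assert zs.z_mm.shape == (2, 2)
        assert zs.observed.e.sum() == pytest.approx(1.0)

    def test_nperm_floor(self, triangle_net):
        with pytest.raises(ValueError, match="n_perm"):
            zscore_mixing(triangle_net, "cell_type", n_perm=1)


class TestImputation:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3), columns=list("abc"))
        out, report = impute_missing_mm(df)
        pd.testing.assert_frame_equal(out, df)
        assert not report.dropped_variables and not report.dropped_samples

    def test_sparse_variable_dropped(self):
        df = pd.DataFrame({
            "dense": np.arange(10.0),
            "sparse": [1.0, 2.0] + [np.nan] * 8,
        })
        out, report = impute_missing_mm(df, min_defined_fraction=0.5)
        assert report.dropped_variables == ["sparse"]
        assert list(out.columns) == ["dense"]

    def test_imputed_value_within_donor_range(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"f1": x, "f2": 2 * x, "f3": 3 * x})
        df.loc[4, "f2"] = np.nan
        out, _ = impute_missing_mm(df, k_neighbors=3)
        donors = df["f2"].dropna()
        assert donors.min() <= out.loc[4, "f2"] <= donors.max()

    def test_nothing_survives_error(self):
        df = pd.DataFrame({"a": [np.nan] * 4, "b": [np.nan] * 4})
        with pytest.raises(ValueError, match="no variable"):
            impute_missing_mm(df)
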