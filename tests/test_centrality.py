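import networkx as nx
import numpy as np
import pandas as pd
import pytest

from multicent.centrality import (
    betweenness,
    centrality_table,
    closeness,
    degree,
    effect_matrix,
    eigenvector,
    normalize_max1,
    topological_importance,
)

from oracles import (
    brute_betweenness,
    brute_closeness,
    brute_topological_importance,
)


class TestWorkedExample:
    """The 9-node tree reproduces every printed value of the worked example
    simultaneously: D=3, TI1~1.58, B=19, C=0.615, EC(b)=0.925, EC(g3)=0.676."""

    def test_all_six_worked_example_values(self, toy_table):
        b = toy_table.loc["b"]
        assert b["D"] == 3
        assert b["TI1"] == pytest.approx(1 + 0.25 + 1 / 3, abs=1e-12)
        assert round(b["TI1"], 2) == pytest.approx(1.58, abs=0.01)
        assert b["B"] == pytest.approx(19.0, abs=1e-9)
        assert b["C"] == pytest.approx(8 / 13, abs=1e-12)
        assert round(b["C"], 3) == 0.615
        assert round(b["EC"], 3) == 0.925
        assert round(toy_table.loc["g3", "EC"], 3) == 0.676
        assert toy_table.loc["g2", "EC"] == pytest.approx(1.0)

    def test_hub_ranks(self, toy_table):
        # the hub is first on the path-based indices but second on EC
        assert toy_table["B"].idxmax() == "b"
        assert toy_table["C"].idxmax() == "b"
        assert toy_table["EC"].rank(ascending=False)["b"] == 2

    def test_table_shape(self, toy_table):
        assert len(toy_table) == 9
        assert toy_table.filter(like="_norm").max().tolist() == [1.0] * 6


class TestDegreeAndEigenvector:
    def test_degree_examples(self, toy):
        assert degree(toy)["b"] == 3
        assert all(v == 3 for v in degree(nx.complete_graph(4)).values())
        g = nx.Graph()
        g.add_node("solo")
        assert degree(g)["solo"] == 0

    def test_complete_graph_symmetry(self):
        ec = eigenvector(nx.complete_graph(5))
        assert all(v == pytest.approx(1.0) for v in ec.values())

    def test_eigen_relation_residual(self, toy):
        ec = eigenvector(toy, tol=1e-12)
        nodes = sorted(toy.nodes())
        a = nx.to_numpy_array(toy, nodelist=nodes)
        v = np.array([ec[n] for n in nodes])
        lam = v @ a @ v / (v @ v)
        assert np.max(np.abs(a @ v - lam * v)) < 1e-9

    def test_node_order_invariance(self, toy):
        relabeled = nx.relabel_nodes(toy, {n: f"zz_{n}" for n in toy.nodes})
        ec1 = eigenvector(toy)
        ec2 = eigenvector(relabeled)
        for n in toy.nodes:
            assert ec2[f"zz_{n}"] == pytest.approx(ec1[n], abs=1e-9)

    def test_disconnected_rejected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="giant"):
            eigenvector(g)

    def test_nonconvergence_reports_residual(self, toy):
        with pytest.raises(RuntimeError, match="residual"):
            eigenvector(toy, tol=1e-15, max_iter=2)


class TestClosenessBetweenness:
    def test_star_center(self):
        g = nx.star_graph(6)
        assert closeness(g)[0] == pytest.approx(1.0)

    def test_path_middle(self):
        assert closeness(nx.path_graph(3))[1] == pytest.approx(1.0)

    def test_leaf_betweenness_zero(self, toy):
        assert betweenness(toy)["w1"] == 0.0

    def test_cycle_fractional_geodesics(self):
        # C4: the opposite pair has two geodesics, each mid-node carries 1/2
        b = betweenness(nx.cycle_graph(4))
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_matches_brute_force_on_random_graphs(self):
        from conftest import random_connected_graph

        rng = np.random.default_rng(42)
        for _ in range(15):
            g = random_connected_graph(rng, n_min=4, n_max=9)
            bb, bc = brute_betweenness(g), brute_closeness(g)
            fb, fc = betweenness(g), closeness(g)
            for v in g.nodes:
                assert fb[v] == pytest.approx(bb[v], abs=1e-9)
                assert fc[v] == pytest.approx(bc[v], abs=1e-9)


class TestEffectMatrixAndTI:
    def test_single_edge(self):
        em = effect_matrix(nx.Graph([("A", "B")]))
        assert em.matrix[0, 1] == 1.0 and em.matrix[1, 0] == 1.0
        assert np.all(np.diagonal(em.matrix) == 0)

    def test_p3_entry(self):
        em = effect_matrix(nx.path_graph(["a", "b", "c"]))
        i, j = em.nodes.index("b"), em.nodes.index("a")
        assert em.matrix[i, j] == 0.5  # effect of a on b is 1/deg(b)

    def test_row_stochastic(self, toy):
        em = effect_matrix(toy)
        assert np.allclose(em.matrix.sum(axis=1), 1.0)

    def test_isolated_node_named_in_error(self):
        g = nx.Graph([("A", "B")])
        g.add_node("LONER")
        with pytest.raises(ValueError, match="LONER"):
            effect_matrix(g)

    def test_ti_m_validation(self, toy):
        with pytest.raises(ValueError, match="m must be >= 1"):
            topological_importance(toy, 0)

    def test_p3_two_step(self):
        ti2 = topological_importance(nx.path_graph(["a", "b", "c"]), 2)
        assert ti2["a"] == pytest.approx(0.5)
        assert ti2["b"] == pytest.approx(1.0)
        assert ti2["c"] == pytest.approx(0.5)

    def test_conservation_sum_equals_n(self):
        from conftest import random_connected_graph

        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_connected_graph(rng)
            ti1 = topological_importance(g, 1)
            assert sum(ti1.values()) == pytest.approx(
                g.number_of_nodes(), abs=1e-9
            )

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_walk_recursion_oracle(self, m):
        from conftest import random_connected_graph

        rng = np.random.default_rng(m)
        for _ in range(8):
            g = random_connected_graph(rng, n_min=4, n_max=8)
            fast = topological_importance(g, m)
            slow = brute_topological_importance(g, m)
            for v in g.nodes:
                assert fast[v] == pytest.approx(slow[v], abs=1e-9)


class TestNormalization:
    def test_column_scaling(self):
        t = pd.DataFrame({"D": [2.0, 4.0]}, index=["a", "b"])
        out = normalize_max1(t)
        assert out["D_norm"].tolist() == [0.5, 1.0]

    def test_idempotent(self, toy_table):
        again = normalize_max1(toy_table)
        pd.testing.assert_frame_equal(again, toy_table)

    def test_zero_column_left_with_warning(self, caplog):
        t = pd.DataFrame({"B": [0.0, 0.0], "D": [1.0, 2.0]}, index=["a", "b"])
        with caplog.at_level("WARNING"):
            out = normalize_max1(t)
        assert "zero maximum" in caplog.text
        assert out["B_norm"].tolist() == [0.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_max1(pd.DataFrame(columns=["D"]))
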