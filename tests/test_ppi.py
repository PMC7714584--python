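"""PPI expansion, centralities, and the two-stage DC -> BC filtration."""

import math

import networkx as nx
import numpy as np
import pytest

from netpharm.exceptions import InputError
from netpharm.ppi import (PPIGraph, betweenness_centrality, degree_centrality,
                          expand_seeds, extract_core, top_fraction_filter)

from conftest import betweenness_naive


def ppi_from_edges(edges, seeds=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    return PPIGraph(g, seeds=set(seeds))


class TestExpandSeeds:
    def test_direct_neighbors_only(self):
        ppi = expand_seeds({"A"}, [("A", "B"), ("B", "C")])
        assert ppi.nodes == {"A", "B"}
        assert ppi.n_edges == 1

    def test_induced_edges_between_neighbors_kept(self):
        ppi = expand_seeds({"A", "C"}, [("A", "B"), ("B", "C")])
        assert ppi.nodes == {"A", "B", "C"}
        assert ppi.n_edges == 2

    def test_seeds_only_mode(self):
        ppi = expand_seeds({"A", "C"}, [("A", "B"), ("B", "C"), ("A", "C")],
                           expansion="seeds-only")
        assert ppi.nodes == {"A", "C"}
        assert ppi.n_edges == 1

    def test_missing_seed_logged_absent_all_is_error(self, caplog):
        ppi = expand_seeds({"A", "ZZ"}, [("A", "B")])
        assert "ZZ" not in ppi.nodes
        assert any("absent" in r.message for r in caplog.records)
        with pytest.raises(InputError):
            expand_seeds({"ZZ"}, [("A", "B")])

    def test_self_loops_and_duplicates_removed(self):
        ppi = expand_seeds({"A"}, [("A", "A"), ("A", "B"), ("B", "A")])
        assert ppi.n_edges == 1


class TestDegreeCentrality:
    def test_triangle(self):
        dc = degree_centrality(ppi_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert dc == {"a": 2, "b": 2, "c": 2}

    def test_star(self):
        dc = degree_centrality(
            ppi_from_edges([("hub", f"l{i}") for i in range(5)])
        )
        assert dc["hub"] == 5
        assert all(dc[f"l{i}"] == 1 for i in range(5))

    def test_equals_adjacency_row_sums(self):
        g = nx.gnp_random_graph(50, 0.1, seed=4)
        ppi = PPIGraph(g)
        nodes = sorted(ppi.nodes)
        adj = nx.to_numpy_array(ppi.graph, nodelist=nodes)
        dc = degree_centrality(ppi)
        np.testing.assert_array_equal(
            np.array([dc[n] for n in nodes]), adj.sum(axis=1).astype(int)
        )


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_centrality(ppi_from_edges([("a", "b"), ("b", "c")]))
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_four_cycle_split_geodesics(self):
        bc = betweenness_centrality(
            ppi_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        )
        assert bc == pytest.approx({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})

    def test_agrees_with_naive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(4, 31))
            p = float(rng.uniform(0.1, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            mine = betweenness_centrality(PPIGraph(g))
            naive = betweenness_naive(g)
            for v in g.nodes:
                assert mine[v] == pytest.approx(naive[v], abs=1e-9)

    def test_agrees_with_networkx(self):
        # independent third implementation as a cross-check
        g = nx.gnp_random_graph(40, 0.15, seed=9)
        mine = betweenness_centrality(PPIGraph(g))
        ref = nx.betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert mine[v] == pytest.approx(ref[v], abs=1e-9)

    def test_disconnected_components_handled(self):
        bc = betweenness_centrality(
            ppi_from_edges([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        )
        assert bc["b"] == 1.0 and bc["y"] == 1.0

    def test_isolated_node_does_not_change_others(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")]
        base = betweenness_centrality(ppi_from_edges(edges))
        g = nx.Graph(edges)
        g.add_node("iso")
        with_iso = betweenness_centrality(PPIGraph(g))
        for v in base:
            assert with_iso[v] == pytest.approx(base[v])
        assert with_iso["iso"] == 0.0

    def test_normalized_variant(self):
        bc = betweenness_centrality(
            ppi_from_edges([("a", "b"), ("b", "c")]), normalized=True
        )
        assert bc["b"] == pytest.approx(1.0)  # 1 / ((3-1)(3-2)/2 * 2)


class TestTopFractionFilter:
    def test_distinct_scores_keep_exact_ceil(self):
        ppi = ppi_from_edges([(f"n{i}", f"n{i + 1}") for i in range(9)])
        scores = {f"n{i}": float(i) for i in range(10)}
        out = top_fraction_filter(ppi, scores, 0.3)
        assert out.nodes == {"n9", "n8", "n7"}

    def test_all_tied_keeps_all(self):
        ppi = ppi_from_edges([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        out = top_fraction_filter(ppi, {n: 1.0 for n in ppi.nodes}, 0.3)
        assert out.nodes == ppi.nodes

    def test_tie_rule_hand_case(self):
        # scores (5,5,5,4,3,2,1,1,1,1), fraction 0.3: k=3, cut=5, keep 3
        ppi = ppi_from_edges([(f"n{i}", f"n{(i + 1) % 10}") for i in range(10)])
        vals = [5, 5, 5, 4, 3, 2, 1, 1, 1, 1]
        scores = {f"n{i}": float(v) for i, v in enumerate(vals)}
        out = top_fraction_filter(ppi, scores, 0.3)
        assert out.nodes == {"n0", "n1", "n2"}

    def test_empty_graph_passes_through(self):
        out = top_fraction_filter(PPIGraph(nx.Graph()), {}, 0.3)
        assert out.n_nodes == 0

    def test_invalid_fraction(self):
        ppi = ppi_from_edges([("a", "b")])
        with pytest.raises(InputError):
            top_fraction_filter(ppi, {"a": 1, "b": 2}, 0.0)


class TestExtractCore:
    def test_fraction_one_is_identity(self):
        ppi = ppi_from_edges([("a", "b"), ("b", "c")], seeds={"a", "c"})
        res = extract_core(ppi, fraction=1.0)
        assert res.core.nodes == res.subnetwork.nodes == ppi.nodes
        assert res.crucial_genes == {"a", "c"}

    def test_nesting_and_crucial_definition(self):
        g = nx.barabasi_albert_graph(120, 3, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        seeds = {f"N{i}" for i in range(0, 40, 4)}
        res = extract_core(PPIGraph(g, seeds=seeds), fraction=0.3)
        assert res.core.nodes <= res.subnetwork.nodes <= res.full.nodes
        assert res.crucial_genes == seeds & res.core.nodes

    def test_bc_recomputed_on_subnetwork_not_inherited(self):
        # star center c dominates BC in the full graph, but in the induced
        # top-DC subnetwork (the path c-x-y) the middle node x takes over;
        # inheriting full-graph BC would pick {c}, recomputing picks {x}
        edges = [("c", f"l{i}") for i in range(6)]
        edges += [("c", "x"), ("x", "y"), ("y", "z")]
        ppi = ppi_from_edges(edges)
        res = extract_core(ppi, fraction=0.3)
        assert res.subnetwork.nodes == {"c", "x", "y"}
        full_bc = betweenness_centrality(ppi)
        assert max(full_bc, key=full_bc.get) == "c"
        assert res.core.nodes == {"x"}

    def test_two_engineered_seed_hubs_are_the_crucial_genes(self):
        # two communities bridged by the seed genes s1-s2; seed x has high
        # degree only inside a community, seed y sits on the padding cycle:
        # both must be eliminated by the cascade, leaving exactly {s1, s2}
        g = nx.Graph()
        c = [f"c{i}" for i in range(6)]
        d = [f"d{i}" for i in range(6)]
        for grp in (c, d):
            for i in range(6):
                for j in range(i + 1, 6):
                    g.add_edge(grp[i], grp[j])
        g.remove_edge("c4", "c5")
        g.remove_edge("d4", "d5")
        for n in c:
            g.add_edge("s1", n)
        for n in d:
            g.add_edge("s2", n)
        g.add_edge("s1", "s2")
        for i in range(4):
            g.add_edge("x", c[i])
        cycle = [f"p{i}" for i in range(30)] + ["y"]
        for i in range(len(cycle)):
            g.add_edge(cycle[i], cycle[(i + 1) % len(cycle)])
        ppi = PPIGraph(g, seeds={"s1", "s2", "x", "y"})
        res = extract_core(ppi, fraction=0.3)
        assert res.crucial_genes == {"s1", "s2"}
        assert "x" not in res.subnetwork.nodes
        assert res.core.n_nodes < res.subnetwork.n_nodes < res.full.n_nodes

    def test_subnetwork_size_matches_ceil_with_continuous_scores(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(10, 80))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            ppi = PPIGraph(g)
            scores = {v: float(rng.normal()) for v in ppi.nodes}
            out = top_fraction_filter(ppi, scores, 0.3)
            assert out.n_nodes == math.ceil(0.3 * ppi.n_nodes)

    def test_empty_graph_is_an_error(self):
        with pytest.raises(InputError):
            extract_core(PPIGraph(nx.Graph()))
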