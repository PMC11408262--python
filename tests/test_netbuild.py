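import networkx as nx
import numpy as np
import pandas as pd
import pytest

import personet as pn
from personet._util import ValidationError
from conftest import make_edge_table
from _oracles import is_minimal_connector_set, seed_component_count


class TestInteractionTable:
    def test_self_loops_dropped_and_duplicates_collapsed(self):
        edges = make_edge_table([
            ("a", "a", "ppi"), ("a", "b", "ppi"), ("a", "b", "ppi"),
            ("a", "b", "tf_gene")])
        table = pn.InteractionTable.from_edges(edges)
        assert len(table.edges) == 2  # same pair on two layers is kept

    def test_mirna_layer_requires_mirna_endpoint(self):
        edges = make_edge_table([("a", "b", "mirna_gene")])
        with pytest.raises(ValidationError):
            pn.InteractionTable.from_edges(edges, node_types={"c": "mirna"})

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValidationError):
            pn.InteractionTable.from_edges(
                make_edge_table([("a", "b", "coexpression")]))


class TestBuildNetwork:
    def test_star_fixture(self, star_interactions):
        net = pn.build_network(["s"], star_interactions, layers=("ppi",))
        assert net.n_nodes == 4
        assert net.graph.number_of_edges() == 3
        assert net.seeds == frozenset({"s"})

    def test_layer_filter_excludes_other_layers(self, star_interactions):
        net = pn.build_network(["s"], star_interactions, layers=("ppi",))
        assert "m1" not in net.nodes
        net_all = pn.build_network(["s"], star_interactions)
        assert "m1" in net_all.nodes

    def test_seed_with_no_edges_kept_isolated_with_warning(self, star_interactions):
        with pytest.warns(UserWarning):
            net = pn.build_network(["s", "ghost"], star_interactions)
        assert "ghost" in net.nodes
        assert net.graph.degree("ghost") == 0

    def test_empty_seed_list_rejected(self, star_interactions):
        with pytest.raises(ValidationError):
            pn.build_network([], star_interactions)


class TestMinimumNetwork:
    def test_prunes_leaf_but_keeps_bridge(self):
        # A-X, X-B, A-Y: X is the unique essential connector, Y a prunable leaf
        edges = make_edge_table([
            ("A", "X", "ppi"), ("X", "B", "ppi"), ("A", "Y", "ppi")])
        net = pn.network_from_edges(edges, seeds=["A", "B"])
        minimal = pn.minimum_network(net)
        assert minimal.nodes == {"A", "X", "B"}
        assert is_minimal_connector_set(net.graph, {"A", "B"}, {"X"})

    def test_all_seed_network_unchanged(self):
        edges = make_edge_table([("A", "B", "ppi"), ("B", "C", "ppi")])
        net = pn.network_from_edges(edges, seeds=["A", "B", "C"])
        minimal = pn.minimum_network(net)
        assert minimal.nodes == net.nodes

    def test_disconnected_seed_components_both_kept(self):
        edges = make_edge_table([("A", "x", "ppi"), ("B", "y", "ppi")])
        net = pn.network_from_edges(edges, seeds=["A", "B"])
        minimal = pn.minimum_network(net)
        assert {"A", "B"} <= minimal.nodes
        assert seed_component_count(minimal.graph, {"A", "B"}) == 2
        assert minimal.nodes == {"A", "B"}  # leaves x, y are inessential

    def test_seed_conservation_and_connector_minimality_on_random_graphs(self):
        # exhaustive oracle check on graphs of <= 12 nodes
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(5, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(10_000)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = set(rng.choice(sorted(g.nodes),
                                   size=int(rng.integers(2, max(3, n // 2))),
                                   replace=False))
            edges = make_edge_table([(u, v, "ppi") for u, v in g.edges])
            net = pn.network_from_edges(edges, seeds=seeds)
            minimal = pn.minimum_network(net)
            assert seeds <= minimal.nodes, "seeds must be conserved"
            retained = minimal.nodes - seeds
            assert is_minimal_connector_set(net.graph, seeds, retained), (
                f"trial {trial}: retained {retained} is not minimal")

    def test_every_connector_lies_on_a_seed_path(self):
        edges = make_edge_table([
            ("A", "c1", "ppi"), ("c1", "c2", "ppi"), ("c2", "B", "ppi"),
            ("c2", "dangling", "ppi")])
        minimal = pn.minimum_network(pn.network_from_edges(edges, seeds=["A", "B"]))
        for node in minimal.connectors:
            without = minimal.graph.copy()
            without.remove_node(node)
            assert seed_component_count(without, {"A", "B"}) > 1


class TestMergeAndHub:
    def test_replication_fixture_sizes(self):
        cfg = pn.SynthConfig()
        ea, sa, eb, sb, types = pn.gen_replication_networks(cfg)
        a = pn.network_from_edges(ea, sa, types)
        b = pn.network_from_edges(eb, sb, types)
        assert (a.n_nodes, b.n_nodes) == (45, 43)
        merged = pn.merge_networks([a, b])
        assert merged.n_nodes == 82
        hub = pn.shared_hub(a, b)
        assert sorted(hub) == ["mirna", "protein_coding"]
        assert len(hub["mirna"]) == 3 and len(hub["protein_coding"]) == 3

    def test_merge_idempotent_and_disjoint_sizes(self):
        e1 = make_edge_table([("a", "b", "ppi"), ("b", "c", "ppi")])
        e2 = make_edge_table([("x", "y", "ppi"), ("y", "z", "ppi"), ("z", "w", "ppi")])
        n1 = pn.network_from_edges(e1, seeds=["a"])
        n2 = pn.network_from_edges(e2, seeds=["x"])
        assert pn.merge_networks([n1, n1]).nodes == n1.nodes
        assert pn.merge_networks([n1, n2]).n_nodes == 7

    def test_merge_commutative_and_associative_on_sets(self):
        e1 = make_edge_table([("a", "b", "ppi")])
        e2 = make_edge_table([("b", "c", "ppi")])
        e3 = make_edge_table([("c", "d", "tf_gene")])
        nets = [pn.network_from_edges(e, seeds=[s])
                for e, s in zip((e1, e2, e3), "abc")]
        ab_c = pn.merge_networks([pn.merge_networks(nets[:2]), nets[2]])
        a_bc = pn.merge_networks([nets[0], pn.merge_networks(nets[1:])])
        cba = pn.merge_networks(nets[::-1])
        def edge_set(net):
            return {frozenset(e) for e in net.graph.edges}
        for m in (a_bc, cba):
            assert m.nodes == ab_c.nodes
            assert edge_set(m) == edge_set(ab_c)
            assert m.seeds == ab_c.seeds

    def test_conflicting_biotypes_rejected(self):
        e = make_edge_table([("a", "b", "ppi")])
        n1 = pn.network_from_edges(e, seeds=["a"], node_types={"b": "mirna"})
        n2 = pn.network_from_edges(e, seeds=["a"], node_types={"b": "lncrna"})
        with pytest.raises(ValidationError):
            pn.merge_networks([n1, n2])

    def test_hub_of_disjoint_and_identical_networks(self):
        e1 = make_edge_table([("a", "b", "ppi")])
        e2 = make_edge_table([("x", "y", "ppi")])
        n1 = pn.network_from_edges(e1, seeds=["a"])
        n2 = pn.network_from_edges(e2, seeds=["x"])
        assert pn.shared_hub(n1, n2) == {}
        full = pn.shared_hub(n1, n1)
        assert sorted(sum(full.values(), [])) == ["a", "b"]


class TestConnectGets:
    def test_planted_bridge_is_returned(self):
        edges = make_edge_table([
            ("g1", "bridge", "ppi"), ("bridge", "h1", "ppi"),
            ("g1", "leaf", "ppi")])
        table = pn.InteractionTable.from_edges(edges)
        out = pn.connect_gets([["g1"], ["h1"]], table)
        assert out == ["bridge"]

    def test_adjacent_gets_need_no_connector(self):
        edges = make_edge_table([("g1", "h1", "ppi")])
        table = pn.InteractionTable.from_edges(edges)
        assert pn.connect_gets([["g1"], ["h1"]], table) == []

    def test_unbridgeable_gets_warn_and_return_empty(self):
        edges = make_edge_table([("g1", "a", "ppi"), ("h1", "b", "ppi")])
        table = pn.InteractionTable.from_edges(edges)
        with pytest.warns(UserWarning):
            out = pn.connect_gets([["g1"], ["h1"]], table)
        assert out == []

    def test_requires_two_sets(self, star_interactions):
        with pytest.raises(ValidationError):
            pn.connect_gets([["s"]], star_interactions)
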