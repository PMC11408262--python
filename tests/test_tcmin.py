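import networkx as nx
import numpy as np
import pytest

import personet as pn
from personet._util import ValidationError
from conftest import make_edge_table
from _oracles import dense_eigenvector_centrality


def hub_table(rows, extra_types=None):
    types = {"m1": "mirna", "m2": "mirna", "m3": "mirna",
             "p1": "protein_coding", "p2": "protein_coding",
             "p3": "protein_coding"}
    types.update(extra_types or {})
    return pn.InteractionTable.from_edges(make_edge_table(rows), node_types=types)


HUB = ["m1", "m2", "m3", "p1", "p2", "p3"]
HUB_ONLY_ROWS = [("m1", "p1", "mirna_gene"), ("m2", "p2", "mirna_gene"),
                 ("m3", "p3", "mirna_gene"), ("p1", "p2", "ppi")]


class TestExpandHub:
    def test_hub_without_interactors_is_six_nodes(self):
        table = hub_table(HUB_ONLY_ROWS)
        net = pn.expand_hub(HUB, table)
        assert set(net.graph.nodes) == set(HUB)
        assert net.n_genes == 0

    def test_missing_hub_member_rejected(self):
        table = hub_table(HUB_ONLY_ROWS[:2])
        with pytest.raises(ValidationError):
            pn.expand_hub(HUB, table)

    def test_nonstandard_hub_warns(self):
        table = hub_table([("m1", "p1", "mirna_gene")])
        with pytest.warns(UserWarning):
            pn.expand_hub(["m1", "p1"], table)

    def test_multi_regulated_gene_appears_once(self):
        rows = HUB_ONLY_ROWS + [("m1", "g", "mirna_gene"), ("m2", "g", "mirna_gene")]
        net = pn.expand_hub(HUB, hub_table(rows, {"g": "protein_coding"}))
        assert list(net.non_hub_nodes) == ["g"]
        modules, _ = pn.regulator_signature_modules(net)
        by_id = {m.module_id: m.members for m in modules}
        assert by_id["M1"] == ["g"]  # signature {m1, m2}

    def test_planted_composition_counts(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        net = pn.expand_hub(truth["hub"], interactions)
        comp = net.biotype_composition()
        assert comp == truth["composition"]
        assert net.n_genes == truth["n_direct_interactors"]
        assert net.n_genes == sum(truth["composition"].values())


class TestSignatureModules:
    def test_planted_module_sizes_recovered(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        net = pn.expand_hub(truth["hub"], interactions)
        modules, unassigned = pn.regulator_signature_modules(net)
        sizes = {m.module_id: len(m.members) for m in modules}
        for mid, members in truth["modules"].items():
            assert sizes[mid] == len(members), mid
        assert len(unassigned) == len(truth["ppi_partners"])

    def test_m1_to_m7_partition_mirna_targeted_genes(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        net = pn.expand_hub(truth["hub"], interactions)
        modules, _ = pn.regulator_signature_modules(net)
        sig_modules = [m for m in modules if m.module_id in
                       {f"M{i}" for i in range(1, 8)}]
        seen = set()
        for m in sig_modules:
            assert seen.isdisjoint(m.members)
            seen.update(m.members)
        targeted = {n for n in net.non_hub_nodes
                    if any(net.graph.has_edge(n, mm) for mm in net.hub_mirnas)}
        assert seen == targeted

    def test_single_mirna_targets_populate_one_module(self):
        rows = HUB_ONLY_ROWS + [("m2", f"g{i}", "mirna_gene") for i in range(4)]
        net = pn.expand_hub(HUB, hub_table(
            rows, {f"g{i}": "protein_coding" for i in range(4)}))
        modules, _ = pn.regulator_signature_modules(net)
        by_id = {m.module_id: m.members for m in modules}
        assert len(by_id["M5"]) == 4  # m2-only signature
        assert all(not by_id[f"M{i}"] for i in (1, 2, 3, 4, 6, 7))

    def test_mirna_on_two_hub_proteins_multi_assigned(self):
        rows = HUB_ONLY_ROWS + [("x", "p1", "mirna_gene"), ("x", "p2", "mirna_gene")]
        net = pn.expand_hub(HUB, hub_table(rows, {"x": "mirna"}))
        modules, _ = pn.regulator_signature_modules(net)
        by_id = {m.module_id: m for m in modules}
        assert by_id["M8"].members == ["x"] and by_id["M9"].members == ["x"]
        assert by_id["M8"].multi_assigned == ["x"]


class TestNodeMetrics:
    def test_star_center_has_maximal_centrality(self):
        g = nx.star_graph(8)
        metrics = pn.node_metrics(g).set_index("node")
        assert metrics.loc[0, "eigenvector"] == pytest.approx(1.0)
        assert (metrics.drop(index=0)["eigenvector"] < 1.0).all()

    def test_triangle_clustering_is_one(self):
        metrics = pn.node_metrics(nx.complete_graph(3))
        assert (metrics["clustering"] == 1.0).all()

    def test_matches_dense_eigen_oracle_on_random_graph(self):
        g = nx.gnp_random_graph(50, 0.12, seed=42)
        metrics = pn.node_metrics(g, tol=1e-12).set_index("node")
        oracle = dense_eigenvector_centrality(g)
        for n, expected in oracle.items():
            assert metrics.loc[n, "eigenvector"] == pytest.approx(expected,
                                                                  abs=1e-6)

    def test_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        relabel = {n: f"node_{n}" for n in g.nodes}
        m1 = pn.node_metrics(g).set_index("node")
        m2 = pn.node_metrics(nx.relabel_nodes(g, relabel)).set_index("node")
        for n in g.nodes:
            assert m1.loc[n, "eigenvector"] == pytest.approx(
                m2.loc[f"node_{n}", "eigenvector"], abs=1e-9)

    def test_minor_components_flagged_zero(self):
        g = nx.Graph([(0, 1), (1, 2), (5, 6)])
        metrics = pn.node_metrics(g).set_index("node")
        assert metrics.loc[5, "eigenvector"] == 0.0
        assert bool(metrics.loc[5, "outside_largest_component"])


class TestCommunities:
    def test_two_cliques_found_with_positive_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        assignment, q = pn.community_detection(g, seed=0)
        assert len(set(assignment.values())) == 2
        # direct modularity formula on the recovered partition
        m = g.number_of_edges()
        degrees = dict(g.degree())
        q_direct = 0.0
        for u in g.nodes:
            for v in g.nodes:
                if assignment[u] == assignment[v]:
                    a_uv = 1.0 if g.has_edge(u, v) else 0.0
                    q_direct += a_uv - degrees[u] * degrees[v] / (2 * m)
        q_direct /= 2 * m
        assert q == pytest.approx(q_direct, abs=1e-12)
        assert q > 0.3

    def test_complete_graph_single_community(self):
        assignment, _ = pn.community_detection(nx.complete_graph(8), seed=0)
        assert len(set(assignment.values())) == 1

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.1, seed=9)
        a1 = pn.community_detection(g, seed=4)
        a2 = pn.community_detection(g, seed=4)
        assert a1 == a2

    def test_empty_edge_set_singletons(self):
        g = nx.empty_graph(5)
        assignment, q = pn.community_detection(g)
        assert len(set(assignment.values())) == 5 and q == 0.0


class TestExtension:
    def test_empty_lnc_table_leaves_network_unchanged(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        net = pn.expand_hub(truth["hub"], interactions)
        empty = make_edge_table([])
        extended, summary = pn.extend_with_lncrna(net, empty, ["LNC-01"])
        assert extended.n_genes == net.n_genes
        assert summary["n_lncrna_interactions"] == 0

    def test_planted_extension_counts(self, interaction_bundle):
        interactions, lnc_edges, truth = interaction_bundle
        net = pn.expand_hub(truth["hub"], interactions)
        extended, summary = pn.extend_with_lncrna(
            net, lnc_edges, truth["extension"]["lncrnas"],
            node_types=truth["extension"]["node_types"])
        assert summary["n_lncrna_interactions"] == truth["extension"]["n_interactions"]
        assert summary["n_lncrnas_linked"] == len(truth["extension"]["lncrnas"])
        assert extended.n_genes == truth["extension"]["n_extended"]
        # conservation: composition counts sum to the gene total
        comp = extended.biotype_composition()
        assert sum(comp.values()) == extended.n_genes
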