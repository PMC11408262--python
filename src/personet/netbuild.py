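"""Seed-based multi-layer interaction networks and minimum-network extraction.

A regulatory network is assembled from a typed edge table (protein-protein,
TF-gene and miRNA-gene layers) around a set of *seed* genes, then pruned to
the *minimum network*: the seeds plus only those non-seed nodes that are
essential to keep the seeds connected.  Two minimum networks can be merged,
and the nodes they share form the candidate control hub.

Edges are treated as undirected for all connectivity purposes; the regulatory
direction of TF-gene and miRNA-gene edges is retained only as layer metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ._util import ValidationError

LAYERS = ("ppi", "tf_gene", "mirna_gene")

#: biotype vocabulary used on every node throughout the package; ``tf`` is a
#: protein-coding subtype and is folded into ``protein_coding`` when biotype
#: compositions are reported.
BIOTYPES = ("protein_coding", "tf", "mirna", "lncrna", "pseudogene", "other_ncrna")


@dataclass
class InteractionTable:
    """Typed multi-layer edge list plus a node -> biotype map.

    Invariants enforced at construction: no self-loops, duplicate
    (source, target, layer) rows collapsed, and every ``mirna_gene`` edge has
    at least one miRNA endpoint.
    """

    edges: pd.DataFrame
    node_types: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: pd.DataFrame,
                   node_types: dict[str, str] | None = None) -> "InteractionTable":
        node_types = dict(node_types or {})
        edges = edges.loc[:, ["source", "target", "layer"]].copy()
        bad_layer = set(edges["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown interaction layers: {sorted(bad_layer)}")
        edges = edges[edges["source"] != edges["target"]]
        edges = edges.drop_duplicates().reset_index(drop=True)
        mirna = {n for n, t in node_types.items() if t == "mirna"}
        mg = edges[edges["layer"] == "mirna_gene"]
        bad = mg[~(mg["source"].isin(mirna) | mg["target"].isin(mirna))]
        if len(bad) and mirna:
            pair = (bad.iloc[0]["source"], bad.iloc[0]["target"])
            raise ValidationError(
                f"mirna_gene edge without a miRNA endpoint, e.g. {pair}")
        return cls(edges=edges, node_types=node_types)

    @property
    def universe(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    def subset(self, layers) -> pd.DataFrame:
        """Rows restricted to the requested layers."""
        layers = list(layers)
        bad = set(layers) - set(LAYERS)
        if bad:
            raise ValidationError(f"unknown layers requested: {sorted(bad)}")
        return self.edges[self.edges["layer"].isin(layers)]


@dataclass
class Network:
    """Undirected network with seed/connector roles and biotype annotations."""

    graph: nx.Graph
    seeds: frozenset

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def connectors(self) -> set[str]:
        return self.nodes - self.seeds

    def biotype_counts(self, collapse_tf: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, data in self.graph.nodes(data=True):
            bt = data.get("biotype", "other_ncrna")
            if collapse_tf and bt == "tf":
                bt = "protein_coding"
            counts[bt] = counts.get(bt, 0) + 1
        return counts

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "role": d.get("role", "connector"),
             "biotype": d.get("biotype", "other_ncrna")}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node", "role", "biotype"])


def _annotate(graph: nx.Graph, seeds, node_types) -> None:
    for n in graph.nodes:
        graph.nodes[n]["role"] = "seed" if n in seeds else "connector"
        graph.nodes[n]["biotype"] = node_types.get(n, "other_ncrna")


def network_from_edges(edges: pd.DataFrame, seeds,
                       node_types: dict[str, str] | None = None) -> Network:
    """Take an explicit edge list as the network, marking the given seeds.

    Unlike :func:`build_network` this performs no neighbourhood expansion; it
    is the entry point for externally curated (or fixture) networks.
    """
    node_types = node_types or {}
    g = nx.Graph()
    seeds = frozenset(seeds)
    g.add_nodes_from(seeds)
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, layer=row.layer)
    _annotate(g, seeds, node_types)
    return Network(graph=g, seeds=seeds)


def build_network(seeds, interactions: InteractionTable,
                  layers=LAYERS) -> Network:
    """First-order network: seeds, their direct neighbours, and all edges
    of the requested layers among the included nodes.

    Seeds missing from the interaction universe are kept as isolated seed
    nodes with a warning.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValidationError("seeds must be non-empty")
    edges = interactions.subset(layers)
    adjacent = edges[(edges["source"].isin(seeds)) | (edges["target"].isin(seeds))]
    nodes = seeds | set(adjacent["source"]) | set(adjacent["target"])
    induced = edges[(edges["source"].isin(nodes)) & (edges["target"].isin(nodes))]
    missing = seeds - interactions.universe
    if missing:
        warnings.warn(
            f"{len(missing)} seed(s) absent from the interaction universe "
            f"kept as isolated nodes: {sorted(missing)[:5]}...")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for row in induced.itertuples(index=False):
        g.add_edge(row.source, row.target, layer=row.layer)
    _annotate(g, seeds, interactions.node_types)
    return Network(graph=g, seeds=seeds)


def _seed_component_count(graph: nx.Graph, seeds) -> int:
    return sum(1 for comp in nx.connected_components(graph) if comp & seeds)


def minimum_network(net: Network) -> Network:
    """Prune non-seed nodes that are not essential for seed connectivity.

    Greedy deterministic rule: repeatedly iterate over non-seed nodes in
    ascending degree (ties broken by ascending betweenness centrality, then
    ascending identifier) and delete a node whenever its removal does not
    increase the number of connected components that contain at least one
    seed.  Iterate to a fixed point.  The retained connector set is minimal:
    removing any single retained connector would split a seed component.
    """
    g = net.graph.copy()
    seeds = set(net.seeds)
    target = _seed_component_count(g, seeds)
    changed = True
    while changed:
        changed = False
        btw = nx.betweenness_centrality(g)
        order = sorted(
            (n for n in g.nodes if n not in seeds),
            key=lambda n: (g.degree(n), btw[n], str(n)),
        )
        for node in order:
            neighbors = list(g.neighbors(node))
            g.remove_node(node)
            if _seed_component_count(g, seeds) <= target:
                changed = True
            else:
                g.add_node(node, **net.graph.nodes[node])
                for nb in neighbors:
                    if nb in g:
                        g.add_edge(node, nb, **net.graph.edges[node, nb])
    _annotate(g, seeds, {n: d.get("biotype") for n, d in net.graph.nodes(data=True)})
    return Network(graph=g, seeds=net.seeds)


def merge_networks(nets: list[Network]) -> Network:
    """Node/edge union; a node is a seed if it is a seed in any input.

    Per-node provenance lists the indices of the contributing networks.
    Conflicting biotype annotations for the same node are an error.
    """
    if len(nets) < 2:
        raise ValidationError("merge_networks requires at least two networks")
    g = nx.Graph()
    seeds: set[str] = set()
    for i, net in enumerate(nets):
        seeds |= set(net.seeds)
        for n, d in net.graph.nodes(data=True):
            if n in g:
                prev = g.nodes[n].get("biotype")
                new = d.get("biotype")
                if prev is not None and new is not None and prev != new:
                    raise ValidationError(
                        f"conflicting biotypes for node {n}: {prev} vs {new}")
                g.nodes[n]["provenance"] = g.nodes[n]["provenance"] + [i]
            else:
                g.add_node(n, biotype=d.get("biotype"), provenance=[i])
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, **d)
    _annotate_merge = {n: g.nodes[n].get("biotype") for n in g.nodes}
    for n in g.nodes:
        g.nodes[n]["role"] = "seed" if n in seeds else "connector"
        g.nodes[n]["biotype"] = _annotate_merge[n] or "other_ncrna"
    return Network(graph=g, seeds=frozenset(seeds))


def shared_hub(net_a: Network, net_b: Network) -> dict[str, list[str]]:
    """Nodes present in both networks, partitioned by biotype."""
    shared = net_a.nodes & net_b.nodes
    out: dict[str, list[str]] = {}
    for n in sorted(shared):
        bt = net_a.graph.nodes[n].get("biotype", "other_ncrna")
        if bt == "tf":
            bt = "protein_coding"
        out.setdefault(bt, []).append(n)
    return out


def connect_gets(get_gene_sets, interactions: InteractionTable,
                 layers=LAYERS) -> list[str]:
    """Connectors joining several gene sets: pool all set genes as seeds,
    build the first-order network, minimize, and return the surviving
    non-seed nodes (sorted)."""
    if len(get_gene_sets) < 2:
        raise ValidationError("need at least two gene sets to connect")
    seeds: set[str] = set()
    for genes in get_gene_sets:
        seeds |= set(genes)
    net = build_network(seeds, interactions, layers=layers)
    minimal = minimum_network(net)
    if _seed_component_count(minimal.graph, set(minimal.seeds)) > 1:
        warnings.warn("gene sets remain in disconnected components")
    return sorted(minimal.connectors)
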