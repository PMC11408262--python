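"""Hub-centred molecular integration network (TCMIN) construction.

The control hub — canonically 3 miRNAs plus 3 protein-coding genes shared
between the two minimum networks — is expanded to all of its direct
interactors on the miRNA-gene and protein-protein layers.  The expanded
network is hub-centric: only hub-interactor and hub-hub edges are kept by
default, reflecting a star topology anchored on the six coordinators (a
flag retains the full induced subgraph instead).

Non-hub genes are partitioned into regulator-signature modules:

* M1..M7 by the exact subset of hub miRNAs that target the gene — with hub
  miRNAs ordered (m1, m2, m3), M1={m1,m2}, M2={m2,m3}, M3={m1,m3},
  M4={m1,m2,m3}, M5={m2}, M6={m3}, M7={m1};
* M8..M10 collect the miRNAs attached to each hub protein-coding gene (in
  hub order).

Node analytics (degree, clustering coefficient, eigenvector centrality by
power iteration, Louvain-style community structure) mirror the standard
network-overview toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._util import ValidationError
from .netbuild import InteractionTable


@dataclass
class TCMIN:
    """Hub plus direct interactors, with biotypes and module assignments."""

    hub: list[str]
    graph: nx.Graph
    hub_mirnas: list[str]
    hub_proteins: list[str]

    @property
    def non_hub_nodes(self) -> set[str]:
        return set(self.graph.nodes) - set(self.hub)

    @property
    def n_genes(self) -> int:
        """Number of genes beside the hub."""
        return len(self.non_hub_nodes)

    def biotype_composition(self, collapse_tf: bool = True) -> dict[str, int]:
        """Counts per biotype over the non-hub genes."""
        counts: dict[str, int] = {}
        for n in self.non_hub_nodes:
            bt = self.graph.nodes[n].get("biotype", "other_ncrna")
            if collapse_tf and bt == "tf":
                bt = "protein_coding"
            counts[bt] = counts.get(bt, 0) + 1
        return counts

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "biotype": d.get("biotype", "other_ncrna"),
             "is_hub": n in set(self.hub)}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node", "biotype", "is_hub"])


@dataclass
class ModuleAssignment:
    module_id: str
    signature: tuple[str, ...]  # defining hub regulators
    members: list[str]
    multi_assigned: list[str] = field(default_factory=list)


def expand_hub(hub, interactions: InteractionTable,
               layers=("mirna_gene", "ppi"),
               full_subgraph: bool = False) -> TCMIN:
    """All direct interactors of the hub on the miRNA-gene and PPI layers.

    ``hub`` is an ordered sequence; its miRNAs and protein-coding members
    are identified from the interaction table's node types.  A hub of other
    than 3 miRNAs + 3 proteins is allowed with a warning.
    """
    hub = list(hub)
    universe = interactions.universe
    for h in hub:
        if h not in universe:
            raise ValidationError(f"hub member {h!r} missing from interaction universe")
    types = interactions.node_types
    hub_mirnas = [h for h in hub if types.get(h) == "mirna"]
    hub_proteins = [h for h in hub if types.get(h) in ("protein_coding", "tf")]
    if len(hub_mirnas) != 3 or len(hub_proteins) != 3:
        warnings.warn(
            f"nonstandard hub composition: {len(hub_mirnas)} miRNAs and "
            f"{len(hub_proteins)} protein-coding genes (canonical is 3 + 3)")
    edges = interactions.subset(layers)
    hub_set = set(hub)
    touching = edges[(edges["source"].isin(hub_set)) | (edges["target"].isin(hub_set))]
    nodes = hub_set | set(touching["source"]) | set(touching["target"])
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if full_subgraph:
        keep = edges[(edges["source"].isin(nodes)) & (edges["target"].isin(nodes))]
    else:
        keep = touching
    for row in keep.itertuples(index=False):
        g.add_edge(row.source, row.target, layer=row.layer)
    for n in g.nodes:
        g.nodes[n]["biotype"] = types.get(n, "other_ncrna")
    return TCMIN(hub=hub, graph=g, hub_mirnas=hub_mirnas,
                 hub_proteins=hub_proteins)


def regulator_signature_modules(tcmin: TCMIN) -> tuple[list[ModuleAssignment], list[str]]:
    """Partition non-hub genes by their hub-miRNA regulator signature.

    Returns ``(modules, unassigned)``.  Genes whose signature is empty and
    that are miRNAs attached to a hub protein go to that protein's module
    (M8..M10); a miRNA attached to several hub proteins is assigned to all
    of them and flagged.  Remaining signature-less genes are reported as
    unassigned (not an error).
    """
    if len(tcmin.hub_mirnas) != 3:
        raise ValidationError(
            "signature modules require exactly 3 hub miRNAs "
            f"(got {len(tcmin.hub_mirnas)})")
    m1, m2, m3 = tcmin.hub_mirnas
    signature_map = {
        frozenset({m1, m2}): ("M1", (m1, m2)),
        frozenset({m2, m3}): ("M2", (m2, m3)),
        frozenset({m1, m3}): ("M3", (m1, m3)),
        frozenset({m1, m2, m3}): ("M4", (m1, m2, m3)),
        frozenset({m2}): ("M5", (m2,)),
        frozenset({m3}): ("M6", (m3,)),
        frozenset({m1}): ("M7", (m1,)),
    }
    g = tcmin.graph
    mirna_adj: dict[str, set[str]] = {}
    for u, v, d in g.edges(data=True):
        if d.get("layer") == "mirna_gene":
            mirna_adj.setdefault(u, set()).add(v)
            mirna_adj.setdefault(v, set()).add(u)
    hub_mirna_set = set(tcmin.hub_mirnas)

    members: dict[str, list[str]] = {mid: [] for mid, _ in signature_map.values()}
    protein_members: dict[str, list[str]] = {p: [] for p in tcmin.hub_proteins}
    multi: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for node in sorted(tcmin.non_hub_nodes):
        sig = frozenset(mirna_adj.get(node, set()) & hub_mirna_set)
        if sig:
            mid, _ = signature_map[sig]
            members[mid].append(node)
            continue
        attached = [p for p in tcmin.hub_proteins if g.has_edge(node, p)
                    and g.nodes[node].get("biotype") == "mirna"]
        if attached:
            for p in attached:
                protein_members[p].append(node)
            if len(attached) > 1:
                multi[node] = attached
        else:
            unassigned.append(node)
    modules = [
        ModuleAssignment(module_id=mid, signature=sig, members=members[mid])
        for sig_set, (mid, sig) in sorted(signature_map.items(),
                                          key=lambda kv: kv[1][0])
    ]
    for i, p in enumerate(tcmin.hub_proteins):
        mid = f"M{8 + i}"
        modules.append(ModuleAssignment(
            module_id=mid, signature=(p,), members=protein_members[p],
            multi_assigned=[n for n in protein_members[p] if n in multi]))
    return modules, unassigned


def node_metrics(graph: nx.Graph, tol: float = 1e-10,
                 max_iter: int = 10_000) -> pd.DataFrame:
    """Degree, clustering coefficient and eigenvector centrality per node.

    Eigenvector centrality is computed by power iteration on (A + I) — the
    diagonal shift makes the dominant eigenvalue strictly largest in
    magnitude on bipartite graphs while leaving the eigenvectors unchanged —
    within the largest connected component, normalized to max = 1; nodes in
    other components score 0 and are flagged.
    """
    nodes = sorted(graph.nodes)
    degree = dict(graph.degree())
    clustering = nx.clustering(graph)
    centrality = {n: 0.0 for n in nodes}
    flagged = {n: False for n in nodes}
    if graph.number_of_nodes():
        components = sorted(nx.connected_components(graph), key=len, reverse=True)
        giant = sorted(components[0])
        for comp in components[1:]:
            for n in comp:
                flagged[n] = True
        if len(giant) == 1:
            centrality[giant[0]] = 1.0
        else:
            sub = graph.subgraph(giant)
            index = {n: i for i, n in enumerate(giant)}
            A = np.zeros((len(giant), len(giant)))
            for u, v in sub.edges:
                A[index[u], index[v]] = 1.0
                A[index[v], index[u]] = 1.0
            x = np.full(len(giant), 1.0 / np.sqrt(len(giant)))
            converged = False
            for _ in range(max_iter):
                y = A @ x + x  # (A + I) x
                y /= np.linalg.norm(y)
                if np.abs(y - x).max() < tol:
                    x = y
                    converged = True
                    break
                x = y
            if not converged:
                residual = float(np.abs((A @ x + x) / np.linalg.norm(A @ x + x) - x).max())
                raise ValidationError(
                    f"eigenvector centrality did not converge; residual={residual:.2e}")
            x = x / x.max()
            for n in giant:
                centrality[n] = float(x[index[n]])
    return pd.DataFrame({
        "node": nodes,
        "degree": [degree[n] for n in nodes],
        "clustering": [float(clustering[n]) for n in nodes],
        "eigenvector": [centrality[n] for n in nodes],
        "outside_largest_component": [flagged[n] for n in nodes],
    })


def community_detection(graph: nx.Graph, resolution: float = 1.0,
                        seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain-style greedy modularity maximization, deterministic per seed.

    Returns (node -> community id, modularity Q).  With no edges every node
    is its own community and Q = 0.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes))}, 0.0
    parts = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
    parts = sorted((sorted(p) for p in parts), key=lambda p: p[0])
    assignment = {n: i for i, p in enumerate(parts) for n in p}
    q = nx.community.modularity(graph, parts, resolution=resolution)
    return assignment, float(q)


def extend_with_lncrna(tcmin: TCMIN, lnc_interactions: pd.DataFrame,
                       personality_lncrnas,
                       node_types: dict[str, str] | None = None) -> tuple[TCMIN, dict]:
    """Add genes linked through personality-associated lncRNA interactions.

    Starting from the personality lncRNAs, every non-lncRNA gene reachable
    in the lncRNA interaction table is added to the network (the lncRNAs
    themselves act as the linking layer and are not counted as network
    genes).  Returns the extended network and a summary with the number of
    lncRNA interactions (edges incident to a personality lncRNA) and of
    linked lncRNAs.
    """
    node_types = dict(node_types or {})
    lncs = set(personality_lncrnas)
    adj: dict[str, set[str]] = {}
    for row in lnc_interactions.itertuples(index=False):
        adj.setdefault(row.source, set()).add(row.target)
        adj.setdefault(row.target, set()).add(row.source)
    # BFS from the personality lncRNAs over the lncRNA interaction layer
    frontier = [l for l in sorted(lncs) if l in adj]
    seen = set(frontier)
    reached: set[str] = set()
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb in seen:
                    continue
                seen.add(nb)
                nxt.append(nb)
                if nb not in lncs:
                    reached.add(nb)
        frontier = nxt
    n_interactions = 0
    for row in lnc_interactions.itertuples(index=False):
        if row.source in lncs or row.target in lncs:
            n_interactions += 1
    linked = {l for l in lncs if l in adj}
    g = tcmin.graph.copy()
    new_nodes = reached - set(g.nodes)
    for n in sorted(new_nodes):
        g.add_node(n, biotype=node_types.get(n, "other_ncrna"))
    for row in lnc_interactions.itertuples(index=False):
        if row.source in lncs or row.target in lncs:
            continue  # lncRNAs are linking metadata, not network nodes
        if row.source in g and row.target in g:
            g.add_edge(row.source, row.target, layer=row.layer)
    extended = TCMIN(hub=tcmin.hub, graph=g, hub_mirnas=tcmin.hub_mirnas,
                     hub_proteins=tcmin.hub_proteins)
    summary = {
        "n_lncrna_interactions": n_interactions,
        "n_lncrnas_linked": len(linked),
        "n_new_genes": len(new_nodes),
        "n_genes_extended": extended.n_genes,
    }
    return extended, summary
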