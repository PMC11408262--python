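"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by enumeration or dense linear algebra
so they stay independent of the implementation paths they check.
"""

from itertools import combinations

import networkx as nx
import numpy as np


def seed_component_count(graph: nx.Graph, seeds) -> int:
    return sum(1 for comp in nx.connected_components(graph) if comp & set(seeds))


def minimal_connector_sets(graph: nx.Graph, seeds):
    """All cardinality-minimal connector subsets preserving seed connectivity.

    Exhaustively enumerates subsets of non-seed nodes (feasible for graphs
    of <= ~12 nodes) and returns every smallest subset S such that the
    subgraph induced on seeds + S has the same number of seed-containing
    components as the full graph.
    """
    seeds = set(seeds)
    connectors = sorted(set(graph.nodes) - seeds)
    target = seed_component_count(graph, seeds)
    for size in range(len(connectors) + 1):
        found = []
        for subset in combinations(connectors, size):
            sub = graph.subgraph(seeds | set(subset))
            if seed_component_count(sub, seeds) == target:
                found.append(set(subset))
        if found:
            return found
    return [set()]


def is_minimal_connector_set(graph: nx.Graph, seeds, retained) -> bool:
    """True iff `retained` preserves seed connectivity and no proper subset does."""
    seeds = set(seeds)
    retained = set(retained)
    target = seed_component_count(graph, seeds)
    sub = graph.subgraph(seeds | retained)
    if seed_component_count(sub, seeds) != target:
        return False
    for node in retained:
        smaller = graph.subgraph(seeds | (retained - {node}))
        if seed_component_count(smaller, seeds) == target:
            return False
    return True


def dense_eigenvector_centrality(graph: nx.Graph) -> dict:
    """Principal eigenvector of the adjacency matrix of the largest
    component via dense symmetric eigendecomposition, normalized max = 1."""
    comp = max(nx.connected_components(graph), key=len)
    nodes = sorted(comp)
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.subgraph(comp).edges:
        A[index[u], index[v]] = 1.0
        A[index[v], index[u]] = 1.0
    w, v = np.linalg.eigh(A)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)
    vec /= vec.max()
    out = {n: 0.0 for n in graph.nodes}
    out.update({n: float(vec[index[n]]) for n in nodes})
    return out


def chi2_closed_form(table: np.ndarray) -> float:
    """Pearson chi-square by the definitional sum over cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())
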