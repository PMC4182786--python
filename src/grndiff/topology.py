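"""Topological descriptors of a directed regulatory network.

Distances follow directed edges (regulator to target); neighbourhood
measures ignore direction.  The summary mirrors the classic descriptive
panel of network-analysis tools: diameter, characteristic path length,
proportion of connected ordered pairs, average neighbour count and the
number of reciprocally linked node pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx

from .inference import RegulatoryNetwork

__all__ = ["TopologySummary", "topology_summary", "closeness_centrality"]


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_tfs: int
    n_targets: int
    n_edges: int
    diameter: int
    characteristic_path_length: float
    reachable_pair_proportion: float
    avg_neighbors: float
    multi_edge_node_pairs: int

    def as_dict(self) -> dict:
        return asdict(self)


def _digraph(net: RegulatoryNetwork | nx.DiGraph) -> nx.DiGraph:
    return net.graph if isinstance(net, RegulatoryNetwork) else net


def multi_edge_pairs(g: nx.DiGraph) -> int:
    """Unordered node pairs joined by reciprocal directed edges."""
    return sum(1 for a, b in g.edges if a < b and g.has_edge(b, a))


def topology_summary(net: RegulatoryNetwork | nx.DiGraph) -> TopologySummary:
    """Directed-path and neighbourhood descriptors of one network.

    Shortest paths are breadth-first over directed edges; the diameter is the
    longest finite distance, the characteristic path length the mean finite
    distance over ordered pairs, and the reachable-pair proportion the share
    of ordered pairs joined by a directed path.  ``avg_neighbors`` counts
    distinct adjacent nodes regardless of direction, so the identity
    ``avg_neighbors = 2 (E - M) / N`` holds, with E directed edges and M
    reciprocally linked pairs.
    """
    g = _digraph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    total = finite = 0
    diameter = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                finite += 1
                total += d
                diameter = max(diameter, d)
    cpl = total / finite if finite else 0.0
    reach = finite / (n * (n - 1)) if n > 1 else 0.0
    und = nx.Graph(g)
    avg_nb = sum(dict(und.degree()).values()) / n
    m = multi_edge_pairs(g)
    n_tfs = sum(1 for _, d in g.out_degree() if d >= 1)
    n_targets = sum(1 for _, d in g.in_degree() if d >= 1)
    return TopologySummary(
        n_nodes=n,
        n_tfs=n_tfs,
        n_targets=n_targets,
        n_edges=g.number_of_edges(),
        diameter=diameter,
        characteristic_path_length=cpl,
        reachable_pair_proportion=reach,
        avg_neighbors=avg_nb,
        multi_edge_node_pairs=m,
    )


def closeness_centrality(net: RegulatoryNetwork | nx.DiGraph) -> dict[str, float]:
    """Harmonic out-closeness on directed distances.

    For node v: sum over nodes reachable from v of 1/d(v, u), divided by
    n - 1.  Harmonic closeness handles the unreachable pairs that directed
    giant components necessarily contain; a node that reaches nothing scores
    0.
    """
    g = _digraph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        return {v: 0.0 for v in g}
    out = {}
    for v in g:
        dists = nx.single_source_shortest_path_length(g, v)
        out[v] = sum(1.0 / d for d in dists.values() if d > 0) / (n - 1)
    return out
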