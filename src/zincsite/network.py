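"""Residue contact graph and per-node graph-theoretic features.

Two residues are in contact when their Calpha atoms lie within a cutoff
(6.5 A by default, boundary inclusive). Node metrics describe the local
packing microenvironment: degree, clustering coefficient, closeness
centrality (Wasserman-Faust scaling for disconnected graphs), unnormalized
betweenness, eccentricity, Harary status (sum of geodesic distances within
the node's component) and ego-network density.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinChain

log = logging.getLogger(__name__)

CONTACT_CUTOFF = 6.5

METRIC_NAMES = ("degree", "clustering", "closeness", "betweenness",
                "eccentricity", "status", "ego_density")


def build_contact_graph(chain: ProteinChain, cutoff: float = CONTACT_CUTOFF) -> nx.Graph:
    """Calpha threshold graph of a chain; nodes are 1-based residue indices."""
    graph = nx.Graph(cutoff=cutoff, chain_id=chain.chain_id)
    idx, coords = [], []
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is None:
            log.warning("residue %s has no Calpha; excluded from contact graph", res.key)
            continue
        idx.append(res.seq_index)
        coords.append(ca.coords)
    graph.add_nodes_from(idx)
    if not coords:
        return graph
    coords = np.array(coords)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff + 1e-9):
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
            graph.add_edge(idx[i], idx[j])
    return graph


def node_metrics(graph: nx.Graph) -> dict[str, dict[int, float]]:
    """All per-node metrics, keyed by metric name then node."""
    if graph.number_of_nodes() == 0:
        return {name: {} for name in METRIC_NAMES}
    degree = dict(graph.degree())
    clustering = nx.clustering(graph)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    eccentricity: dict[int, float] = {}
    status: dict[int, float] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            node = next(iter(comp))
            eccentricity[node] = 0.0
            status[node] = 0.0
            continue
        for node, dists in nx.all_pairs_shortest_path_length(sub):
            eccentricity[node] = float(max(dists.values()))
            status[node] = float(sum(dists.values()))
    ego_density = {}
    for node in graph:
        ego = nx.ego_graph(graph, node)
        ego_density[node] = nx.density(ego) if len(ego) > 1 else 0.0
    return {
        "degree": {n: float(v) for n, v in degree.items()},
        "clustering": dict(clustering),
        "closeness": dict(closeness),
        "betweenness": dict(betweenness),
        "eccentricity": eccentricity,
        "status": status,
        "ego_density": ego_density,
    }


def graph_density(graph: nx.Graph) -> float:
    """Whole-graph edge density, emitted alongside the node-level metrics."""
    return nx.density(graph)


def metrics_array(metric: dict[int, float], chain_length: int) -> np.ndarray:
    """Per-position array (1-based positions -> index-1); missing nodes get 0."""
    out = np.zeros(chain_length)
    for node, value in metric.items():
        if 1 <= node <= chain_length:
            out[node - 1] = value
    return out


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{graph.graph.get('chain_id', '?')}:{u}\t"
                     f"{graph.graph.get('chain_id', '?')}:{v}\n")
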