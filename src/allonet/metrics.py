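"""Node-level topology metrics in the Cytoscape NetworkAnalyzer dialect.

Six metrics per node, all on the simple undirected unweighted graph (edge
signs and correlation strengths are annotations, never distances):

- degree: number of incident edges.
- eccentricity: maximum shortest-path distance to any node in the same
  connected component; 0 for isolated nodes.
- stress: number of shortest paths between other node pairs on which the
  node lies as an interior vertex. Each unordered (s, t) pair contributes
  once per distinct geodesic by default; a flag exposes the doubled
  ordered-pairs convention some tools use.
- clustering coefficient: fraction of realized edges among the node's
  neighbours; 0 for degree < 2.
- neighbourhood connectivity: mean degree of the node's neighbours; 0 for
  isolated nodes.
- topological coefficient: for node v with >= 2 neighbours,
  ``mean_m J(v, m) / degree(v)`` over all nodes m != v that share at least
  one neighbour with v or are adjacent to it, where J(v, m) counts common
  neighbours plus 1 if (v, m) is itself an edge; 0 for degree < 2.

Distances are computed by breadth-first search with geodesic counting;
stress accumulates sigma(s, v) * sigma(v, t) over pairs satisfying
d(s, v) + d(v, t) = d(s, t).
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

__all__ = [
    "METRIC_NAMES",
    "eccentricity",
    "stress",
    "clustering_coefficient",
    "neighbourhood_connectivity",
    "topological_coefficient",
    "compute_all_metrics",
]

METRIC_NAMES = (
    "degree",
    "eccentricity",
    "stress",
    "topological_coefficient",
    "neighbourhood_connectivity",
    "clustering_coefficient",
)


def _bfs_counts(adj: dict, source) -> tuple[dict, dict]:
    """Distances and geodesic counts from one source (unweighted BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = sigma[u]
                queue.append(w)
            elif dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _adjacency(network: nx.Graph) -> dict:
    return {u: set(network.neighbors(u)) - {u} for u in network.nodes}


def eccentricity(network: nx.Graph) -> dict:
    """Max BFS distance within the node's component; isolated nodes get 0."""
    adj = _adjacency(network)
    out = {}
    for v in adj:
        dist, _ = _bfs_counts(adj, v)
        out[v] = max(dist.values())
    return out


def stress(network: nx.Graph, *, ordered_pairs: bool = False) -> dict:
    """Geodesics through each node as interior vertex.

    ``ordered_pairs=True`` counts each (s, t) pair in both orders (the
    convention of some tools), doubling every value.
    """
    adj = _adjacency(network)
    nodes = list(adj)
    dist, sigma = {}, {}
    for v in nodes:
        dist[v], sigma[v] = _bfs_counts(adj, v)
    out = dict.fromkeys(nodes, 0)
    for i, s in enumerate(nodes):
        ds, ss = dist[s], sigma[s]
        for t in nodes[i + 1 :]:
            if t not in ds:
                continue
            d_st = ds[t]
            dt, st_ = dist[t], sigma[t]
            for v in nodes:
                if v == s or v == t:
                    continue
                if v in ds and 0 < ds[v] < d_st and ds[v] + dt[v] == d_st:
                    out[v] += ss[v] * st_[v]
    if ordered_pairs:
        out = {v: 2 * c for v, c in out.items()}
    return out


def clustering_coefficient(network: nx.Graph) -> dict:
    adj = _adjacency(network)
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        nbr_list = list(nbrs)
        links = sum(
            1
            for i, a in enumerate(nbr_list)
            for b in nbr_list[i + 1 :]
            if b in adj[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def neighbourhood_connectivity(network: nx.Graph) -> dict:
    adj = _adjacency(network)
    return {
        v: (sum(len(adj[w]) for w in nbrs) / len(nbrs)) if nbrs else 0.0
        for v, nbrs in adj.items()
    }


def topological_coefficient(network: nx.Graph) -> dict:
    adj = _adjacency(network)
    out = {}
    for v, nbrs in adj.items():
        if len(nbrs) < 2:
            out[v] = 0.0
            continue
        scores = []
        for m in adj:
            if m == v:
                continue
            shared = len(nbrs & adj[m])
            adjacent = m in nbrs
            if shared == 0 and not adjacent:
                continue
            scores.append(shared + (1 if adjacent else 0))
        out[v] = (sum(scores) / len(scores)) / len(nbrs) if scores else 0.0
    return out


def compute_all_metrics(network: nx.Graph, *, ordered_pairs: bool = False) -> pd.DataFrame:
    """All six metrics for every node (isolated nodes included).

    Returns a DataFrame indexed by node with one column per metric, in
    ``METRIC_NAMES`` order.
    """
    nodes = list(network.nodes)
    cols = {
        "degree": {v: network.degree(v) for v in nodes},
        "eccentricity": eccentricity(network),
        "stress": stress(network, ordered_pairs=ordered_pairs),
        "topological_coefficient": topological_coefficient(network),
        "neighbourhood_connectivity": neighbourhood_connectivity(network),
        "clustering_coefficient": clustering_coefficient(network),
    }
    df = pd.DataFrame({m: [cols[m][v] for v in nodes] for m in METRIC_NAMES}, index=nodes)
    df.index.name = "node"
    return df
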