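"""Independent brute-force reference implementations used as test oracles.

Everything here works on a raw numpy adjacency matrix and deliberately uses
different algorithms from the package: Floyd-Warshall for distances,
exhaustive recursive enumeration of geodesics for stress, direct set
arithmetic for the local coefficients.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = float("inf")


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def enumerate_geodesics(adj: np.ndarray, s: int, t: int, dist: np.ndarray):
    """All shortest s-t paths, found by recursive descent along the
    distance gradient."""
    if dist[s, t] == INF:
        return
    path = [s]

    def step(u):
        if u == t:
            yield list(path)
            return
        for w in np.flatnonzero(adj[u]):
            if dist[u, t] == dist[w, t] + 1:
                path.append(int(w))
                yield from step(int(w))
                path.pop()

    yield from step(s)


def brute_metrics(adj: np.ndarray, ordered_pairs: bool = False) -> dict:
    """All six node metrics by exhaustive computation.

    Returns a dict of metric name -> list of per-node values (node order =
    adjacency row order).
    """
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    degree = adj.sum(axis=1).astype(int).tolist()

    ecc = []
    for v in range(n):
        finite = dist[v][dist[v] < INF]
        ecc.append(int(finite.max()))

    stress = [0] * n
    for s, t in itertools.combinations(range(n), 2):
        for path in enumerate_geodesics(adj, s, t, dist):
            for v in path[1:-1]:
                stress[v] += 1
    if ordered_pairs:
        stress = [2 * x for x in stress]

    clustering = []
    neighbourhood = []
    topo = []
    nbrs = [set(np.flatnonzero(adj[v]).tolist()) for v in range(n)]
    for v in range(n):
        k = len(nbrs[v])
        if k < 2:
            clustering.append(0.0)
        else:
            links = sum(
                1 for a, b in itertools.combinations(sorted(nbrs[v]), 2) if adj[a, b]
            )
            clustering.append(2.0 * links / (k * (k - 1)))
        neighbourhood.append(
            sum(len(nbrs[w]) for w in nbrs[v]) / k if k else 0.0
        )
        if k < 2:
            topo.append(0.0)
            continue
        scores = []
        for m in range(n):
            if m == v:
                continue
            shared = len(nbrs[v] & nbrs[m])
            adjacent = bool(adj[v, m])
            if shared == 0 and not adjacent:
                continue
            scores.append(shared + (1 if adjacent else 0))
        topo.append((sum(scores) / len(scores)) / k if scores else 0.0)

    return {
        "degree": degree,
        "eccentricity": ecc,
        "stress": stress,
        "topological_coefficient": topo,
        "neighbourhood_connectivity": neighbourhood,
        "clustering_coefficient": clustering,
    }


def spearman_rho_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-then-product-moment with mid-ranks, via sorting only."""

    def midrank(a):
        order = np.argsort(a, kind="stable")
        ranks = np.empty(len(a), dtype=float)
        i = 0
        a_sorted = a[order]
        while i < len(a):
            j = i
            while j + 1 < len(a) and a_sorted[j + 1] == a_sorted[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_exact_p_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p by full enumeration over all n! orderings."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho_obs = abs(spearman_rho_oracle(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        if abs(spearman_rho_oracle(x, np.array(perm))) >= rho_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mwu_u_oracle(x, y) -> float:
    """U by literal pair counting: #(x_i > y_j) + 0.5 * #(x_i == y_j)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_exact_p_oracle(x, y) -> float:
    """Two-sided exact p by enumerating all group assignments."""
    x = list(x)
    y = list(y)
    n1 = len(x)
    pooled = x + y
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = mwu_u_oracle(x, y)
    threshold = abs(u_obs - mu) - 1e-9
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in idx]
        if abs(mwu_u_oracle(chosen, rest) - mu) >= threshold:
            count += 1
        total += 1
    return count / total
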