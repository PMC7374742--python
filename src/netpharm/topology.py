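"""Graph-theoretic statistics for protein-interaction networks.

Covers the classical interactome descriptors — degree distribution with a
log-log power-law fit, clustering coefficients, characteristic path length,
shortest-path betweenness, harmonic closeness — plus the BottleNeck score
used by hub-ranking tools: the number of single-source BFS shortest-path
trees in which a node carries more than a quarter of the tree's root-paths.

Conventions (chosen to match the unnormalized magnitudes hub-ranking tools
print): betweenness is an unnormalized pair count with endpoints excluded
and each unordered pair counted once; closeness is the harmonic sum of
reciprocal distances; path length averages over reachable pairs only.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import InteractionNetwork

__all__ = [
    "NodeMetrics",
    "PowerLawFit",
    "NetworkSummary",
    "degree_histogram",
    "fit_power_law",
    "clustering_coefficient",
    "average_clustering",
    "characteristic_path_length",
    "betweenness",
    "harmonic_closeness",
    "bottleneck_scores",
    "compute_node_metrics",
    "summarize",
]


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    degree: int
    clustering_coefficient: float
    betweenness: float
    closeness: float
    bottleneck: int

    @property
    def name(self) -> str:  # CSV column alias
        return self.node


@dataclass(frozen=True)
class PowerLawFit:
    """y = a * k**b fitted by ordinary least squares in log10-log10 space."""
    coefficient_a: float
    exponent_b: float
    r_squared: float
    points_used: int


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    characteristic_path_length: float


def degree_histogram(net: InteractionNetwork) -> list[tuple[int, int]]:
    """(k, n(k)) pairs for k >= 1, ascending in k; isolated nodes excluded."""
    if net.n_nodes == 0:
        raise ValueError("empty network has no degree distribution")
    g = net.to_networkx()
    counts: dict[int, int] = {}
    for _, k in g.degree:
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    return sorted(counts.items())


def fit_power_law(points: list[tuple[float, float]]) -> PowerLawFit:
    """Fit n(k) = a * k**b by OLS of log10 n(k) on log10 k.

    Requires at least two points with distinct k; all k >= 1 and n(k) > 0.
    R^2 is the coefficient of determination on the log-log scale (defined as
    1 when the response is constant, i.e. a perfect horizontal fit).
    """
    if len(points) < 2:
        raise ValueError("power-law fit needs >=2 points")
    ks = np.asarray([p[0] for p in points], dtype=float)
    ns = np.asarray([p[1] for p in points], dtype=float)
    if np.any(ks < 1) or np.any(ns <= 0):
        raise ValueError("power-law fit needs k >= 1 and n(k) > 0")
    if len(np.unique(ks)) < 2:
        raise ValueError("power-law fit needs >=2 distinct k values")
    x = np.log10(ks)
    y = np.log10(ns)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a numerically constant response is a perfect horizontal fit
    if ss_tot <= 1e-20 * max(1.0, float(np.sum(y * y))):
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(coefficient_a=float(10.0 ** intercept),
                       exponent_b=float(slope),
                       r_squared=float(r2),
                       points_used=len(points))


def clustering_coefficient(net: InteractionNetwork, v: str) -> float:
    """C(v) = 2 * (edges among neighbours) / (deg * (deg - 1)); 0 if deg < 2."""
    if v not in net.nodes:
        raise KeyError(v)
    return float(nx.clustering(net.to_networkx(), v))


def average_clustering(net: InteractionNetwork) -> float:
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return float(sum(nx.clustering(net.to_networkx()).values()) / net.n_nodes)


def characteristic_path_length(net: InteractionNetwork) -> float:
    """Mean shortest-path length over unordered *connected* pairs.

    Unreachable pairs are excluded from both numerator and denominator, so the
    statistic is defined for disconnected graphs as long as one connected pair
    exists.
    """
    g = net.to_networkx()
    total = 0
    npairs = 0
    for source, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if target > source:  # each unordered pair once
                total += d
                npairs += 1
    if npairs == 0:
        raise ValueError("network has no connected pair of nodes")
    return total / npairs


def betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes), endpoints excluded,
    each unordered source-target pair counted once, fractional credit when
    shortest paths tie."""
    g = net.to_networkx()
    # networkx with normalized=False already halves undirected counts, i.e.
    # counts each unordered pair once.
    return {n: float(b) for n, b in
            nx.betweenness_centrality(g, normalized=False).items()}


def harmonic_closeness(net: InteractionNetwork) -> dict[str, float]:
    """Clo(v) = sum over reachable u != v of 1/d(v, u)."""
    g = net.to_networkx()
    return {n: float(c) for n, c in nx.harmonic_centrality(g).items()}


def _bfs_tree_lex(adj: dict[str, list[str]], root: str) -> dict[str, str]:
    """BFS shortest-path tree with lexicographic parent tie-breaking: each
    reachable node's parent is the lexicographically smallest neighbour one
    step closer to the root.  Returns child -> parent (root absent)."""
    dist = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    parent: dict[str, str] = {}
    for v, d in dist.items():
        if v == root:
            continue
        parent[v] = min(u for u in adj[v] if dist.get(u) == d - 1)
    return parent


def bottleneck_scores(net: InteractionNetwork) -> dict[str, int]:
    """BottleNeck score of every node.

    For each root s, build the BFS shortest-path tree T_s (ties between
    equal-distance parents broken lexicographically).  For a non-root tree
    node v, let p_s(v) be the number of tree nodes whose path to the root
    passes through v, counting v itself.  Node v earns one point from s iff
    p_s(v) > |V(T_s)| / 4 (strict).  The score is the total over all roots.
    """
    nodes = sorted(net.nodes)
    adj = {n: sorted(net.neighbors(n)) for n in nodes}
    scores = {n: 0 for n in nodes}
    for root in nodes:
        parent = _bfs_tree_lex(adj, root)
        tree_size = len(parent) + 1  # include the root
        # p(v) = subtree size of v in the shortest-path tree
        p = {n: 1 for n in parent}
        # accumulate child subtree sizes upward; order children before parents
        # by processing in reverse BFS (farther nodes first)
        order = sorted(parent, key=lambda n: -_depth(parent, n))
        for v in order:
            par = parent[v]
            if par != root:
                p[par] += p[v]
        for v, pv in p.items():
            if pv > tree_size / 4:
                scores[v] += 1
    return scores


def _depth(parent: dict[str, str], v: str) -> int:
    d = 0
    while v in parent:
        v = parent[v]
        d += 1
    return d


def compute_node_metrics(net: InteractionNetwork) -> list[NodeMetrics]:
    """All per-node metrics, sorted by bottleneck score descending then name."""
    g = net.to_networkx()
    cc = nx.clustering(g)
    btw = betweenness(net)
    clo = harmonic_closeness(net)
    bn = bottleneck_scores(net)
    recs = [
        NodeMetrics(node=n, degree=g.degree(n),
                    clustering_coefficient=float(cc[n]),
                    betweenness=btw[n], closeness=clo[n], bottleneck=bn[n])
        for n in sorted(net.nodes)
    ]
    recs.sort(key=lambda r: (-r.bottleneck, r.node))
    return recs


def summarize(net: InteractionNetwork) -> NetworkSummary:
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        average_degree=2.0 * net.n_edges / net.n_nodes,
        average_clustering=average_clustering(net),
        characteristic_path_length=characteristic_path_length(net),
    )
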