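"""Independent brute-force oracles used by the tests.

Everything here is written for clarity over speed and deliberately avoids
the library's own code paths (and networkx's algorithms): distances by
hand-rolled BFS, betweenness by explicit path enumeration, the bottleneck
score by an explicit tree walk, hypergeometric tails by binomial-coefficient
summation, regression by the normal equations.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def edges_to_adj(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path as a node tuple (BFS layered DFS)."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                extend(path + [w])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness_oracle(nodes, edges):
    """Fractional-credit betweenness, unordered pairs, endpoints excluded."""
    adj = edges_to_adj(nodes, edges)
    score = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def harmonic_closeness_oracle(nodes, edges):
    adj = edges_to_adj(nodes, edges)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def clustering_oracle(nodes, edges):
    adj = edges_to_adj(nodes, edges)
    out = {}
    eset = {frozenset(e) for e in edges}
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if frozenset((a, b)) in eset)
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def path_length_oracle(nodes, edges):
    """Mean distance over unordered connected pairs (Floyd-Warshall style)."""
    nodes = sorted(nodes)
    INF = float("inf")
    d = {a: {b: (0 if a == b else INF) for b in nodes} for a in nodes}
    for u, v in edges:
        d[u][v] = d[v][u] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[a][b] for a, b in itertools.combinations(nodes, 2)
            if d[a][b] < INF]
    if not vals:
        raise ValueError("no connected pair")
    return sum(vals) / len(vals)


def bottleneck_oracle(nodes, edges):
    """Independent tree-walking bottleneck score.

    For each root: build the BFS tree taking, for every node, the
    lexicographically smallest parent among its shortest-path predecessors;
    then count, for each non-root v, the tree nodes whose root-path contains
    v (walking parent pointers up from every node), and award a point when
    that count strictly exceeds a quarter of the tree size.
    """
    adj = edges_to_adj(nodes, edges)
    score = {n: 0 for n in nodes}
    for root in sorted(nodes):
        dist = bfs_distances(adj, root)
        parent = {}
        for v in dist:
            if v == root:
                continue
            preds = [u for u in adj[v] if dist.get(u) == dist[v] - 1]
            parent[v] = min(preds)
        tree_size = len(dist)
        counts = {v: 0 for v in parent}
        for v in dist:
            u = v
            while u != root:
                counts[u] += 1
                u = parent[u]
        for v, c in counts.items():
            if c > tree_size / 4:
                score[v] += 1
    return score


def kcore_weight_oracle(nodes, edges, v):
    """Peel-and-score oracle for the core-clustering vertex weight."""
    adj = edges_to_adj(nodes, edges)
    closed = adj[v] | {v}
    sub = {n: adj[n] & closed for n in closed}
    if all(not nb for nb in sub.values()):
        return 0.0
    # iterative peeling to find the highest k-core
    best_k, best_nodes = 0, set()
    k = 1
    while True:
        cur = {n: set(nb) for n, nb in sub.items()}
        changed = True
        while changed:
            changed = False
            drop = [n for n, nb in cur.items() if len(nb) < k]
            for n in drop:
                for m in cur[n]:
                    cur[m].discard(n)
                del cur[n]
                changed = True
        if not cur:
            break
        best_k, best_nodes = k, set(cur)
        k += 1
    n = len(best_nodes)
    m = sum(len(sub[a] & best_nodes) for a in best_nodes) // 2
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    return best_k * density


def hypergeom_pmf_oracle(x, N, K, n):
    return comb(K, x) * comb(N - K, n - x) / comb(N, n)


def hypergeom_two_sided_oracle(k, K, n, N):
    lo = max(0, n - (N - K))
    hi = min(K, n)
    p_over = sum(hypergeom_pmf_oracle(x, N, K, n) for x in range(k, hi + 1))
    p_under = sum(hypergeom_pmf_oracle(x, N, K, n) for x in range(lo, k + 1))
    return min(1.0, 2.0 * min(p_over, p_under))


def kappa_oracle(a, b, universe):
    a, b, universe = set(a), set(b), set(universe)
    n = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    p_e = (len(a) * len(b) + (n - len(a)) * (n - len(b))) / (n * n)
    if p_e == 1.0:
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def ols_loglog_oracle(points):
    """Slope/intercept of log10 y on log10 x by explicit normal equations."""
    import math
    xs = [math.log10(p[0]) for p in points]
    ys = [math.log10(p[1]) for p in points]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
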