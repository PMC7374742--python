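"""Molecular-complex (MCODE-style) detection of dense network modules.

The algorithm follows the classical three stages: (1) vertex weighting by
the density of the highest k-core of each node's closed neighbourhood,
scaled by k; (2) complex prediction by seeding at the highest-weight
unvisited vertex and breadth-first including neighbours whose weight is
within ``node_score_cutoff`` of the seed's; (3) post-processing — "haircut"
(iteratively strip members with fewer than two connections inside the
module) and optional "fluff" (absorb boundary nodes with dense
neighbourhoods), then a 2-core existence filter.  A module's score is its
internal edge density times its size, so tighter, larger complexes rank
first.

All tie-breaks (seed choice, expansion order) are lexicographic so results
are deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .network_io import InteractionNetwork

__all__ = ["MCODEParams", "Module", "vertex_weight", "vertex_weights",
           "find_modules", "module_score"]


@dataclass(frozen=True)
class MCODEParams:
    """Detection parameters; the defaults are the plugin's documented ones."""
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.degree_cutoff < 2:
            raise ValueError("degree_cutoff must be >= 2")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")


@dataclass
class Module:
    members: frozenset[str]
    seed_vertex: str
    score: float
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, induced subgraph of the highest k-core); (0, empty) if none."""
    if g.number_of_edges() == 0:
        return 0, nx.Graph()
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    members = [n for n, k in core_num.items() if k == k_max]
    return k_max, g.subgraph(members).copy()


def vertex_weight(net: InteractionNetwork, v: str) -> float:
    """Core-clustering weight of ``v``: k_max x density of the highest
    k-core of the subgraph induced by v and its neighbours; isolated
    vertices weigh 0."""
    if v not in net.nodes:
        raise KeyError(v)
    return _weight_one(net.to_networkx(), v)


def _weight_one(g: nx.Graph, v: str) -> float:
    # low-degree vertices keep their weight for inclusion decisions; the
    # degree cutoff only bars them from seeding (applied in find_modules)
    nbrs = set(g.neighbors(v))
    if not nbrs:
        return 0.0
    gv = g.subgraph(nbrs | {v})
    k_max, core = _highest_k_core(gv)
    if k_max == 0:
        return 0.0
    return k_max * _density(core)


def vertex_weights(net: InteractionNetwork) -> dict[str, float]:
    g = net.to_networkx()
    return {v: _weight_one(g, v) for v in g.nodes}


def module_score(net: InteractionNetwork, members: frozenset[str] | set[str]) -> float:
    """density x size of the induced subgraph; singletons are an error."""
    members = set(members)
    if not members <= net.nodes:
        raise ValueError("members must be a subset of the network's nodes")
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    sub = net.to_networkx().subgraph(members)
    return _density(sub) * len(members)


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    members = set(members)
    changed = True
    while changed:
        changed = False
        sub = g.subgraph(members)
        drop = {n for n in members if sub.degree(n) < 2}
        if drop:
            members -= drop
            changed = True
    return members


def _fluff(g: nx.Graph, members: set[str], density_cutoff: float) -> set[str]:
    extra: set[str] = set()
    for v in sorted(members):
        for u in sorted(g.neighbors(v)):
            if u in members or u in extra:
                continue
            closed = set(g.neighbors(u)) | {u}
            if _density(g.subgraph(closed)) > density_cutoff:
                extra.add(u)
    return members | extra


def find_modules(net: InteractionNetwork,
                 params: MCODEParams | None = None) -> list[Module]:
    """Predict dense modules, returned in descending score order.

    Seeds are taken in descending vertex weight (ties lexicographic),
    skipping already-visited vertices and vertices below the degree cutoff.
    Expansion is breadth-first from the seed: a neighbour joins when its
    weight >= seed_weight * (1 - node_score_cutoff) and it has not been
    visited by any earlier complex, up to ``max_depth`` hops from the seed.
    Haircut and (optional) fluff follow; modules lacking a 2-core when
    ``k_core_filter`` = 2, or with fewer than 2 members, are discarded.
    """
    params = params or MCODEParams()
    g = net.to_networkx()
    weights = {v: _weight_one(g, v) for v in g.nodes}
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []

    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    for seed in order:
        if seed in visited or g.degree(seed) < params.degree_cutoff:
            continue
        if weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        queue = deque([(seed, 0)])
        while queue:
            u, depth = queue.popleft()
            if depth >= params.max_depth:
                continue
            for w in sorted(g.neighbors(u)):
                if w in visited:
                    continue
                if weights[w] >= threshold:
                    visited.add(w)
                    members.add(w)
                    queue.append((w, depth + 1))
        raw.append((seed, members))

    modules: list[Module] = []
    for seed, members in raw:
        if params.haircut:
            members = _haircut(g, members)
        if params.fluff:
            members = _fluff(g, members, params.fluff_density_cutoff)
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        if params.k_core_filter >= 2:
            k_max, _ = _highest_k_core(sub)
            if k_max < params.k_core_filter:
                continue
        if not nx.is_connected(sub):
            # keep the component containing the seed (haircut/fluff can in
            # principle split a complex; the seed's component is the module)
            if seed in members:
                comp = nx.node_connected_component(sub, seed)
            else:
                comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
            members = set(comp)
            sub = g.subgraph(members)
            if len(members) < 2:
                continue
        dens = _density(sub)
        modules.append(Module(members=frozenset(members), seed_vertex=seed,
                              score=dens * len(members), density=dens))
    modules.sort(key=lambda m: (-m.score, m.seed_vertex))
    return modules
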