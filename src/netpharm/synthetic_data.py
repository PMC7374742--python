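"""Seeded generators and transcribed in-text fixtures.

The generators produce the graph, annotation and kinetic inputs every stage
of the pipeline needs for testing: preferential-attachment (scale-free) and
Erdős–Rényi graphs, graphs with planted cliques for module-detection
recovery, annotation universes with one planted enriched term, and a toy
mass-action cascade with closed-form-checkable pieces.  All are
bit-reproducible under a fixed seed.

The two fixtures transcribe the published candidate table (22 proteins with
bottleneck / betweenness / closeness / clustering-coefficient / degree) and
the published 17 functional groups with their associated genes.
Transcription policy: only cells that segment unambiguously from the
printed table are pinned; ambiguous betweenness/closeness cells are stored
as ``None`` and never asserted on.  The printed alias IL8 is stored under
its Table-2 spelling CXCL8 so gene names join across fixtures.
"""

from __future__ import annotations

import numpy as np

from .enrichment import TermGroup
from .kinetics import KineticModel, parse_reaction_text
from .network_io import AnnotationSet, InteractionNetwork
from .prioritize import CandidateRow

__all__ = [
    "scale_free_graph",
    "random_graph",
    "planted_modules_graph",
    "annotation_with_planted_term",
    "table1_fixture",
    "table2_fixture",
    "table2_annotation",
    "toy_cascade_model",
]


def _node(i: int) -> str:
    return f"P{i:04d}"


def scale_free_graph(n: int, m: int, seed: int) -> InteractionNetwork:
    """Preferential-attachment graph, pinned variant.

    Start from a star on m+1 nodes (node 0 is the hub); each arriving node
    attaches to m distinct existing nodes sampled proportionally to degree.
    No multi-edges, so the edge count is exactly (n - m) * m.
    """
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n (got m={m}, n={n})")
    rng = np.random.default_rng(seed)
    net = InteractionNetwork()
    # degree-weighted urn: node label repeated once per incident edge
    urn: list[int] = []
    for i in range(1, m + 1):
        net.add_edge(_node(0), _node(i))
        urn += [0, i]
    for i in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(urn[rng.integers(len(urn))])
        for t in sorted(targets):
            net.add_edge(_node(i), _node(t))
            urn += [i, t]
    return net


def random_graph(n: int, p: float, seed: int) -> InteractionNetwork:
    """Erdős–Rényi G(n, p): each unordered pair independently with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    net = InteractionNetwork()
    for i in range(n):
        net.add_node(_node(i))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(_node(i), _node(j))
    return net


def planted_modules_graph(background_n: int, background_p: float,
                          clique_sizes: list[int], seed: int
                          ) -> tuple[InteractionNetwork, list[set[str]]]:
    """ER background with disjoint planted cliques, each wired to the
    background by a single random bridge edge.  Returns the network and the
    planted member sets (in input order)."""
    if any(s < 3 for s in clique_sizes):
        raise ValueError("clique sizes must be >= 3")
    rng = np.random.default_rng(seed)
    net = random_graph(background_n, background_p, seed)
    planted: list[set[str]] = []
    for ci, size in enumerate(clique_sizes):
        members = [f"C{ci}_{j:03d}" for j in range(size)]
        for a in range(size):
            for b in range(a + 1, size):
                net.add_edge(members[a], members[b])
        anchor = members[int(rng.integers(size))]
        bg = _node(int(rng.integers(background_n)))
        net.add_edge(anchor, bg)
        planted.append(set(members))
    return net, planted


def annotation_with_planted_term(universe_n: int = 1000, n_terms: int = 20,
                                 term_size: int = 40, planted_overlap: int = 20,
                                 query_size: int = 25, seed: int = 0
                                 ) -> tuple[AnnotationSet, set[str]]:
    """Annotation universe with one term enriched in the query.

    The planted term receives ``planted_overlap`` of the query's genes; the
    rest of the query and all other terms are drawn uniformly.  Defaults:
    a 1000-gene universe, a 40-gene planted term holding 20 of the 25 query
    genes — a strong but not degenerate enrichment signal.
    """
    if planted_overlap > min(term_size, query_size):
        raise ValueError("planted_overlap cannot exceed term or query size")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(universe_n)]
    perm = rng.permutation(universe_n)
    planted_hits = [genes[i] for i in perm[:planted_overlap]]
    term_fill = [genes[i] for i in perm[planted_overlap:term_size]]
    query_fill = [genes[i] for i in perm[term_size:term_size + (query_size - planted_overlap)]]
    query = set(planted_hits) | set(query_fill)

    ann = AnnotationSet()
    ann.universe = set(genes)
    ann.add_term("T_PLANTED", "planted enriched term",
                 planted_hits + term_fill)
    for t in range(1, n_terms):
        members = rng.choice(universe_n, size=term_size, replace=False)
        ann.add_term(f"T{t:03d}", f"background term {t}",
                     [genes[i] for i in members])
    ann.universe = set(genes)  # background terms may not cover the universe
    return ann, query


# --------------------------------------------------------------- fixtures

# (name, bottleneck, betweenness, closeness, clustering coeff, degree, role)
# None marks a cell whose printed value could not be segmented unambiguously.
_TABLE1 = [
    ("CREBBP", 52, 13223.35, 155.8333, 0.15837, 50, "seed"),
    ("TP53",   22, 7640.317, 148.4167, 0.17639, 38, "seed"),
    ("RELA",   14, 4458.032, 149.0833, 0.20863, 51, "seed"),
    ("MAPK1",  13, 4779.75,  146.5,    0.18316, 47, "seed"),
    ("NFKB1",  11, 3211.738, 144.8333, 0.22304, 44, "seed"),
    ("CYP1A1", 10, 4831.488, 110.8667, 0.43137, 18, "seed"),
    ("SRC",     9, 2899.138, 135.6667, 0.17424, 33, "seed"),
    ("BRCA1",   9, None,     None,     0.38413, 36, "seed"),
    ("EDN1",    9, None,     None,     0.29412, 18, "seed"),
    ("ATR",     9, None,     None,     0.38391, 30, "seed"),
    ("RB1",     7, None,     None,     0.29445, 38, "connector"),
    ("SP1",     7, None,     None,     0.34762, 21, "seed"),
    ("CASP8",   6, 2299.261, 123.3667, 0.4152,  19, "seed"),
    ("STAT1",   6, 1012.291, 130.1667, 0.36594, 24, "seed"),
    ("CREB1",   6, 597.4255, 121.6667, 0.30882, 17, "seed"),
    ("AKT1",    5, 2328.794, 137.4167, 0.17094, 27, "seed"),
    ("CXCL8",   5, 2227.319, 121.1667, 0.4058,  24, "seed"),  # printed as IL8
    ("CDH1",    5, 1162.138, None,     0.34848, 12, "seed"),
    ("KRAS",    5, 917.6512, 120.8333, 0.25692, 23, "seed"),
    ("SYK",     5, 796.2624, 123.6667, 0.24265, 17, "seed"),
    ("CCR5",    5, 669.6932, 108.3667, 0.42222, 10, "seed"),
    ("HDAC3",   5, 471.1578, 124.3333, 0.35263, 20, "seed"),
]

_TABLE2 = [
    ("KEGG:04137", "Mitophagy",
     ["KRAS", "RELA", "SP1", "SRC", "TP53"]),
    ("R-HSA:10906", "Intrinsic pathway for apoptosis",
     ["AKT1", "CASP8", "TP53"]),
    ("KEGG:05167", "Kaposi's sarcoma-associated herpes virus infection",
     ["AKT1", "CASP8", "CCR5", "CREB1", "CREBBP", "CXCL8", "KRAS", "MAPK1",
      "NFKB1", "RB1", "RELA", "SRC", "STAT1", "SYK", "TP53"]),
    ("KEGG:04210", "Apoptosis",
     ["AKT1", "CASP8", "KRAS", "MAPK1", "NFKB1", "RELA", "TP53"]),
    ("KEGG:04926", "Relaxin signalling pathway",
     ["AKT1", "CREB1", "EDN1", "KRAS", "MAPK1", "NFKB1", "RELA", "SRC"]),
    ("KEGG:05161", "Hepatitis B",
     ["AKT1", "CASP8", "CREB1", "CREBBP", "CXCL8", "KRAS", "MAPK1", "NFKB1",
      "RB1", "RELA", "SRC", "STAT1", "TP53"]),
    ("KEGG:05218", "Melanoma",
     ["AKT1", "CDH1", "KRAS", "MAPK1", "RB1", "TP53"]),
    ("KEGG:04919", "Thyroid hormone signalling pathway",
     ["AKT1", "CREBBP", "HDAC3", "KRAS", "MAPK1", "SRC", "STAT1", "TP53"]),
    ("R-HSA:8940973", "RUNX2 regulates osteoblast differentiation",
     ["HDAC3", "MAPK1", "RB1", "SRC"]),
    ("KEGG:05203", "Viral carcinogenesis",
     ["CASP8", "CCR5", "CREB1", "CREBBP", "HDAC3", "KRAS", "MAPK1", "NFKB1",
      "RB1", "RELA", "SRC", "SYK", "TP53"]),
    ("KEGG:04066", "HIF-1 signalling pathway",
     ["AKT1", "CREBBP", "EDN1", "MAPK1", "NFKB1", "RELA"]),
    ("KEGG:05165", "Human papilloma virus infection",
     ["AKT1", "ATR", "CASP8", "CREB1", "CREBBP", "HDAC3", "KRAS", "MAPK1",
      "NFKB1", "RB1", "RELA", "STAT1", "TP53"]),
    ("KEGG:05212", "Pancreatic cancer",
     ["AKT1", "KRAS", "MAPK1", "NFKB1", "RB1", "RELA", "STAT1", "TP53"]),
    ("R-HSA:8878166", "Transcriptional regulation by RUNX2",
     ["AKT1", "HDAC3", "MAPK1", "RB1", "SRC", "STAT1"]),
    ("KEGG:05215", "Prostate cancer",
     ["AKT1", "CREB1", "CREBBP", "KRAS", "MAPK1", "NFKB1", "RB1", "RELA",
      "TP53"]),
    ("KEGG:04062", "Chemokine signalling pathway",
     ["AKT1", "CCR5", "CXCL8", "KRAS", "MAPK1", "NFKB1", "RELA", "SRC",
      "STAT1"]),
    ("KEGG:05152", "Tuberculosis",
     ["AKT1", "CASP8", "CREB1", "CREBBP", "MAPK1", "NFKB1", "RELA", "SRC",
      "STAT1", "SYK"]),
]


def table1_fixture() -> list[CandidateRow]:
    """The 22 top-bottleneck candidate proteins with their topology metrics
    (21 seed proteins plus the connector RB1)."""
    return [CandidateRow(name=n, bottleneck=bn, betweenness=btw, closeness=clo,
                         clustering_coefficient=cc, degree=deg, role=role)
            for (n, bn, btw, clo, cc, deg, role) in _TABLE1]


def table2_fixture() -> list[TermGroup]:
    """The 17 published functional groups (0..16) with associated genes."""
    return [TermGroup(group_id=i, member_terms=[term_id],
                      associated_genes=sorted(genes))
            for i, (term_id, _name, genes) in enumerate(_TABLE2)]


def table2_annotation() -> AnnotationSet:
    """The 17 functional groups as an annotation set (GMT-exportable)."""
    ann = AnnotationSet()
    for term_id, name, genes in _TABLE2:
        ann.add_term(term_id, name, genes)
    return ann


def toy_cascade_model() -> KineticModel:
    """Three-tier toy phosphorylation cascade with explicit enzyme
    mechanisms.  Conserved moieties (all in µM): E total 0.1 = E + EA;
    A total 1 = A + EA + Ap + ApB; B total 1 = B + ApB + Bp + BpC;
    C total 1 = C + BpC + Cp."""
    text = """
    E = 0.1
    A = 1.0
    B = 1.0
    C = 1.0
    A + E <-> EA ; kf=1.0 kr=0.5
    EA -> E + Ap ; kf=0.3
    Ap + B <-> ApB ; kf=1.0 kr=0.5
    ApB -> Ap + Bp ; kf=0.3
    Bp + C <-> BpC ; kf=1.0 kr=0.5
    BpC -> Bp + Cp ; kf=0.3
    """
    return parse_reaction_text(text, name="toy_cascade")
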