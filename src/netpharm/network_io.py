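"""Readers and writers for the file formats the pipeline touches.

Edge lists arrive as STRING-style exports (``protein1  protein2
combined_score`` with scores on the 0-1000 scale); gene-set annotations as
GMT; per-node topology tables as CSV.  All parsing normalizes into two small
containers, :class:`InteractionNetwork` and :class:`AnnotationSet`, which the
rest of the package consumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "InteractionNetwork",
    "AnnotationSet",
    "read_string_tsv",
    "write_string_tsv",
    "write_sif",
    "read_sif",
    "read_gmt",
    "write_gmt",
    "write_metrics_csv",
    "read_metrics_csv",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = [
    "name",
    "bottleneck",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "degree",
]


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """Undirected simple protein-interaction graph.

    Nodes are protein identifiers (case-sensitive strings), each labelled
    ``seed`` (literature-derived) or ``connector`` (database-added linker).
    Edges carry an integer confidence score in [0, 1000]; every topology
    computation in the package treats the graph as unweighted.
    """

    nodes: set[str] = field(default_factory=set)
    node_role: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)
    edge_score: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_node(self, node: str, role: str = "connector") -> None:
        self.nodes.add(node)
        self.node_role.setdefault(node, role)

    def add_edge(self, u: str, v: str, score: int = 1000) -> None:
        if u == v:
            return
        if not 0 <= score <= 1000:
            raise ValueError(f"edge score {score} outside [0, 1000]")
        self.add_node(u)
        self.add_node(v)
        e = _canonical(u, v)
        self.edges.add(e)
        self.edge_score[e] = int(score)

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical(u, v) in self.edges

    def neighbors(self, v: str) -> set[str]:
        if v not in self.nodes:
            raise KeyError(v)
        out = set()
        for a, b in self.edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def degree(self, v: str) -> int:
        return len(self.neighbors(v))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v) in self.edges:
            g.add_edge(u, v, score=self.edge_score.get((u, v), 1000))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph,
                      seed_nodes: Iterable[str] | None = None) -> "InteractionNetwork":
        net = cls()
        seeds = set(seed_nodes or ())
        for n in g.nodes:
            net.add_node(str(n), "seed" if str(n) in seeds else "connector")
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            net.add_edge(str(u), str(v), int(data.get("score", 1000)))
        return net

    def validate(self) -> None:
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if (u, v) != _canonical(u, v):
                raise ValueError(f"edge {(u, v)} not canonically ordered")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {(u, v)} has endpoint outside node set")
            s = self.edge_score.get((u, v))
            if s is None or not 0 <= s <= 1000:
                raise ValueError(f"edge {(u, v)} score {s} outside [0, 1000]")


@dataclass
class AnnotationSet:
    """A gene universe with named gene sets (GO terms, KEGG pathways...)."""

    universe: set[str] = field(default_factory=set)
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add_term(self, term_id: str, name: str, genes: Iterable[str]) -> None:
        members = frozenset(genes)
        if not members:
            raise ValueError(f"term {term_id!r} has no member genes")
        self.terms[term_id] = (name, members)
        self.universe |= members

    def term_genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


def read_string_tsv(path: str | Path, score_threshold: int = 900,
                    seed_nodes: Sequence[str] | None = None) -> InteractionNetwork:
    """Read a STRING-style edge export into an :class:`InteractionNetwork`.

    Each data row is ``protein1 <ws> protein2 [<ws> combined_score]`` with the
    combined score on STRING's integer 0-1000 scale (a missing third column is
    treated as 1000).  Edges scoring below ``score_threshold`` are dropped,
    duplicate orientations (A-B / B-A) collapse to one undirected edge, and
    self-loops are removed.  Nodes named in ``seed_nodes`` are labelled
    ``seed``; every other node is a ``connector``.

    A header line whose third field is not an integer is skipped; any other
    malformed line raises :class:`ParseError` naming the line number.  An
    empty post-filter result is a valid empty network, not an error.
    """
    if not 0 <= score_threshold <= 1000:
        raise ValueError(f"score_threshold {score_threshold} outside [0, 1000]")
    path = Path(path)
    seeds = set(seed_nodes or ())
    net = InteractionNetwork()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected >=2 columns, got {len(fields)}")
            u, v = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    score = int(fields[2])
                except ValueError:
                    if lineno == 1:  # tolerated header row
                        continue
                    raise ParseError(
                        f"{path.name}:{lineno}: score {fields[2]!r} is not an integer"
                    ) from None
            else:
                score = 1000
            if not 0 <= score <= 1000:
                raise ParseError(f"{path.name}:{lineno}: score {score} outside [0, 1000]")
            if u == v:
                continue
            if score < score_threshold:
                continue
            net.add_edge(u, v, score)
    for n in net.nodes:
        net.node_role[n] = "seed" if n in seeds else "connector"
    return net


def write_string_tsv(net: InteractionNetwork, path: str | Path) -> None:
    """Write the edge list back out in STRING export layout (with header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.edge_score.get((u, v), 1000)}\n")


def write_sif(net: InteractionNetwork, path: str | Path) -> None:
    """Write edges as SIF ``A pp B`` lines in lexicographic order."""
    path = Path(path)
    with path.open("w") as fh:
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\tpp\t{v}\n")


def read_sif(path: str | Path,
             seed_nodes: Sequence[str] | None = None) -> InteractionNetwork:
    """Read a SIF file written by :func:`write_sif` (scores default to 1000)."""
    path = Path(path)
    seeds = set(seed_nodes or ())
    net = InteractionNetwork()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3 or fields[1] != "pp":
                raise ParseError(f"{path.name}:{lineno}: expected 'A pp B'")
            if fields[0] != fields[2]:
                net.add_edge(fields[0], fields[2])
    for n in net.nodes:
        net.node_role[n] = "seed" if n in seeds else "connector"
    return net


def read_gmt(path: str | Path,
             universe: Iterable[str] | None = None) -> AnnotationSet:
    """Read a GMT gene-set file (``term_id TAB description TAB gene...``).

    The universe defaults to the union of all member genes unless an explicit
    one is given.  Duplicate genes within a line are stored once; a line with
    fewer than three fields raises :class:`ParseError` with its line number.
    """
    path = Path(path)
    ann = AnnotationSet()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line needs term, description "
                    f"and >=1 gene (got {len(fields)} fields)"
                )
            ann.add_term(fields[0], fields[1], [g for g in fields[2:] if g])
    if universe is not None:
        extra = set(universe)
        missing = ann.universe - extra
        if missing:
            raise ValueError(
                f"explicit universe is missing {len(missing)} annotated genes "
                f"(e.g. {sorted(missing)[:3]})"
            )
        ann.universe = extra
    return ann


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term_id in sorted(ann.terms):
            name, genes = ann.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def write_metrics_csv(metrics: Sequence[Mapping | object], path: str | Path) -> None:
    """Write per-node topology records as CSV mirroring the candidate-table
    layout (name, bottleneck, betweenness, closeness, clustering coefficient,
    degree).  Accepts mappings or objects with those attributes; floats are
    written at full repr precision so a round-trip is lossless.
    """
    path = Path(path)

    def get(rec, key):
        if isinstance(rec, Mapping):
            val = rec.get(key, rec.get("node") if key == "name" else None)
        else:
            val = getattr(rec, key, getattr(rec, "node", None) if key == "name" else None)
        return val

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRICS_COLUMNS)
        for rec in metrics:
            writer.writerow([repr(get(rec, c)) if isinstance(get(rec, c), float)
                             else get(rec, c) for c in METRICS_COLUMNS])


def read_metrics_csv(path: str | Path) -> list[dict]:
    """Read a metrics CSV back into a list of plain dict records."""
    path = Path(path)
    out: list[dict] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != METRICS_COLUMNS:
            raise ParseError(f"{path.name}: unexpected header {reader.fieldnames}")
        for row in reader:
            out.append({
                "name": row["name"],
                "bottleneck": int(row["bottleneck"]),
                "betweenness": float(row["betweenness"]),
                "closeness": float(row["closeness"]),
                "clustering_coefficient": float(row["clustering_coefficient"]),
                "degree": int(row["degree"]),
            })
    return out
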