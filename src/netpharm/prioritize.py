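"""Key-protein selection cascade.

Four steps, applied in order to a per-node topology table and a set of
enrichment groups:

1. keep nodes whose bottleneck score sits in the top *k* distinct score
   levels (ties kept — "top 10 bottleneck" means ten score values, not ten
   rows);
2. date-hub filter: keep candidates with clustering coefficient strictly
   below a threshold (default 0.5) — low co-clustering hubs bind their
   partners sequentially and are the better intervention points;
3. count, for every candidate, the number of enrichment groups whose
   associated genes contain it (pathway coverage; absent nodes count 0);
4. select candidates whose coverage is at least the sample median of all
   candidates' coverages (zeros included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import TermGroup

__all__ = [
    "CandidateRow",
    "PrioritizationResult",
    "top_bottleneck",
    "date_hub_filter",
    "pathway_coverage",
    "median_cutoff_select",
    "run_prioritization",
]


@dataclass(frozen=True)
class CandidateRow:
    """One row of the candidate table (mirrors the node-metrics record).

    ``betweenness``/``closeness`` may be None when the source table left them
    unstated or ambiguous; the cascade never uses those two columns.
    """
    name: str
    bottleneck: int
    betweenness: float | None
    closeness: float | None
    clustering_coefficient: float
    degree: int
    role: str = "seed"


@dataclass
class PrioritizationResult:
    candidates: list[str]
    coverage: dict[str, int]
    median_cutoff: float
    key_proteins: list[str]


def _row_attr(row, key: str):
    if isinstance(row, Mapping):
        return row.get(key, row.get("node") if key == "name" else None)
    return getattr(row, key, getattr(row, "node", None) if key == "name" else None)


def top_bottleneck(table: Sequence, k_levels: int = 10) -> list[str]:
    """Nodes whose bottleneck score is among the ``k_levels`` largest
    *distinct* score values, ties all kept, sorted by score desc then name."""
    if not table:
        raise ValueError("empty candidate table")
    if k_levels < 1:
        raise ValueError("k_levels must be >= 1")
    scores = {_row_attr(r, "name"): int(_row_attr(r, "bottleneck")) for r in table}
    levels = sorted(set(scores.values()), reverse=True)[:k_levels]
    cutoff = min(levels)
    keep = [(s, n) for n, s in scores.items() if s >= cutoff]
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [n for _, n in keep]


def date_hub_filter(nodes: Iterable[str], table: Sequence,
                    cc_threshold: float = 0.5) -> list[str]:
    """Keep nodes whose clustering coefficient is strictly below the
    threshold (the date-hub criterion); order of ``nodes`` preserved."""
    cc = {_row_attr(r, "name"): float(_row_attr(r, "clustering_coefficient"))
          for r in table}
    missing = [n for n in nodes if n not in cc]
    if missing:
        raise KeyError(f"nodes absent from table: {missing[:3]}")
    return [n for n in nodes if cc[n] < cc_threshold]


def pathway_coverage(groups: Sequence[TermGroup],
                     nodes: Iterable[str]) -> dict[str, int]:
    """Per-node count of enrichment groups whose associated genes contain it."""
    memberships = [set(g.associated_genes) for g in groups]
    return {n: sum(1 for genes in memberships if n in genes) for n in nodes}


def median_cutoff_select(coverage: Mapping[str, int]) -> tuple[float, list[str]]:
    """Sample median of all coverage counts (zeros included) and the nodes
    with coverage >= median, sorted by coverage desc then name."""
    if not coverage:
        raise ValueError("empty coverage map")
    med = float(np.median(list(coverage.values())))
    selected = [(c, n) for n, c in coverage.items() if c >= med]
    selected.sort(key=lambda t: (-t[0], t[1]))
    return med, [n for _, n in selected]


def run_prioritization(table: Sequence, groups: Sequence[TermGroup],
                       k_levels: int = 10,
                       cc_threshold: float = 0.5) -> PrioritizationResult:
    """Compose the four cascade steps on a candidate table and groups."""
    top = top_bottleneck(table, k_levels=k_levels)
    candidates = date_hub_filter(top, table, cc_threshold=cc_threshold)
    coverage = pathway_coverage(groups, candidates)
    median, key = median_cutoff_select(coverage)
    return PrioritizationResult(candidates=candidates, coverage=coverage,
                                median_cutoff=median, key_proteins=key)
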