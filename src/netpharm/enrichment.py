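"""Functional enrichment with term grouping.

Per-term significance uses a two-sided hypergeometric test (doubled smaller
tail, capped at 1) with Bonferroni correction over the tested terms.
Significant terms are then merged into groups wherever the Cohen kappa
agreement between their gene-membership vectors over the universe reaches a
threshold (default 0.4); groups are the connected components of that
kappa graph, numbered by descending size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .network_io import AnnotationSet

__all__ = [
    "EnrichmentRecord",
    "TermGroup",
    "hypergeom_two_sided",
    "bonferroni",
    "kappa_score",
    "group_terms",
    "enrich",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's hypergeometric result.

    k = |query ∩ term|, K = term size, n = query size, N = universe size.
    """
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_two_sided: float
    p_bonferroni: float


@dataclass
class TermGroup:
    group_id: int
    member_terms: list[str]
    associated_genes: list[str] = field(default_factory=list)


def hypergeom_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided hypergeometric p: min(1, 2 * min(P(X>=k), P(X<=k))).

    X ~ Hypergeometric(N, K, n): the overlap of a size-n draw with a
    size-K annotated set in a size-N universe.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K <= N and n <= N (got K={K}, n={n}, N={N})")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    dist = hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))   # P(X >= k)
    p_under = float(dist.cdf(k))     # P(X <= k)
    return min(1.0, 2.0 * min(p_over, p_under))


def bonferroni(pvals: Sequence[float], m: int) -> list[float]:
    """Elementwise min(1, m*p), order preserved; m >= len(pvals)."""
    if m < len(pvals):
        raise ValueError(f"m={m} smaller than the number of p-values {len(pvals)}")
    out = []
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(min(1.0, m * p))
    return out


def kappa_score(genes_a: Iterable[str], genes_b: Iterable[str],
                universe: Iterable[str]) -> float:
    """Cohen's kappa between two gene sets' membership vectors over the
    universe: kappa = (p_o - p_e) / (1 - p_e), with kappa defined as 1 when
    chance agreement p_e = 1 (possible only when both vectors are constant
    and identical)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(genes_a)
    b = set(genes_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    n = len(universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    p_o = (n11 + n00) / n
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if p_e == 1.0:
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def group_terms(records: Sequence[EnrichmentRecord],
                term_gene_hits: Mapping[str, Iterable[str]],
                universe: Iterable[str],
                kappa_threshold: float = 0.4) -> list[TermGroup]:
    """Partition filtered terms into kappa-linked groups.

    An edge joins two terms when the kappa between their query-hit sets
    reaches ``kappa_threshold``; groups are the connected components,
    numbered from 0 in descending size (ties by lexicographically smallest
    member term).  Each group's associated genes are the sorted union of its
    member terms' query hits.
    """
    universe = set(universe)
    terms = [r.term_id for r in records]
    hits = {t: set(term_gene_hits[t]) for t in terms}

    # union-find over the kappa graph
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            if kappa_score(hits[t1], hits[t2], universe) >= kappa_threshold:
                parent[find(t2)] = find(t1)

    comps: dict[str, list[str]] = {}
    for t in terms:
        comps.setdefault(find(t), []).append(t)
    comp_list = sorted(comps.values(),
                       key=lambda ms: (-len(ms), min(ms)))
    groups = []
    for gid, members in enumerate(comp_list):
        genes = sorted(set().union(*(hits[t] for t in members)))
        groups.append(TermGroup(group_id=gid, member_terms=sorted(members),
                                associated_genes=genes))
    return groups


def enrich(query: Iterable[str], annotation: AnnotationSet,
           alpha: float = 0.05,
           bonferroni_all_terms: bool = False) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of a gene query against an annotation set.

    Query genes outside the universe are dropped with a warning giving their
    count; one record is computed per term overlapping the query, the Bonferroni
    factor m is the number of tested (k >= 1) terms unless
    ``bonferroni_all_terms`` is set, and records with corrected p < alpha are
    returned in ascending p order.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    inside = query & annotation.universe
    n_dropped = len(query) - len(inside)
    if n_dropped:
        warnings.warn(f"{n_dropped} query gene(s) outside the annotation "
                      "universe were dropped", stacklevel=2)
    if not inside:
        raise ValueError("no query gene is in the annotation universe")
    N = len(annotation.universe)
    n = len(inside)
    tested = []
    for term_id in sorted(annotation.terms):
        name, members = annotation.terms[term_id]
        k = len(inside & members)
        if k >= 1:
            tested.append((term_id, name, k, len(members)))
    m = len(annotation.terms) if bonferroni_all_terms else len(tested)
    records = []
    for term_id, name, k, K in tested:
        p = hypergeom_two_sided(k, K, n, N)
        p_adj = min(1.0, m * p)
        if p_adj < alpha:
            records.append(EnrichmentRecord(term_id=term_id, term_name=name,
                                            k=k, K=K, n=n, N=N,
                                            p_two_sided=p, p_bonferroni=p_adj))
    records.sort(key=lambda r: (r.p_two_sided, r.term_id))
    return records
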