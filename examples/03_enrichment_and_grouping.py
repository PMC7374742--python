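"""Hypergeometric enrichment with kappa-score term grouping.

Generates an annotation universe with one term enriched in the query, runs
the two-sided hypergeometric test with Bonferroni correction, and groups
the surviving terms by Cohen-kappa agreement of their gene memberships.
"""

from netpharm.enrichment import enrich, group_terms
from netpharm.synthetic_data import annotation_with_planted_term

ann, query = annotation_with_planted_term(seed=0)
print(f"universe={len(ann.universe)} genes, {len(ann)} terms, "
      f"query={len(query)} genes")

records = enrich(query, ann, alpha=0.05)
for r in records:
    print(f"  {r.term_id}: k={r.k}/K={r.K}  p={r.p_two_sided:.3g}  "
          f"p_bonf={r.p_bonferroni:.3g}")

hits = {r.term_id: query & ann.term_genes(r.term_id) for r in records}
groups = group_terms(records, hits, ann.universe, kappa_threshold=0.4)
print(f"{len(records)} significant term(s) in {len(groups)} group(s)")
# Only the planted term survives Bonferroni at alpha=0.05: 20 of its 40
# genes appear in a 25-gene query drawn from a 1000-gene universe, an
# overlap a null draw essentially never reaches.
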