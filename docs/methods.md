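# Methods

This note records the models and conventions behind each stage, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices that make results deterministic.

## Network model and topology conventions

Networks are undirected simple graphs over case-sensitive protein
identifiers. Edge confidence scores (STRING's 0–1000 integer scale) are kept
for filtering but **ignored by all topology computations** — the metrics
mirror the unweighted conventions of the standard interactome-analysis
tools, whose printed magnitudes (betweenness in the thousands, closeness
far above 1) imply unnormalized pair counts and reciprocal-distance sums.
Specifically:

- *Betweenness*: Brandes shortest-path betweenness, endpoints excluded,
  each unordered pair counted once, fractional credit across tied shortest
  paths, no normalization.
- *Closeness*: harmonic centrality, Σ_{u≠v} 1/d(v,u); unreachable nodes
  contribute 0, so the statistic is defined on disconnected graphs.
- *Characteristic path length*: mean distance over unordered **reachable**
  pairs only; a graph with no connected pair has no path length (error).
- *Clustering*: C(v)=0 for degree < 2; the network value is the plain mean
  over all nodes, isolated nodes included.
- *BottleNeck score*: no closed-form definition circulates beyond "the node
  carries most of a shortest-path tree", so the tree construction is pinned:
  BFS trees from every root with each node's parent the lexicographically
  smallest neighbour one step closer to the root; v is counted in its own
  subtree; v scores a point from root s iff its subtree holds strictly more
  than |T_s|/4 of the tree's nodes; the root itself never scores. The
  pinning makes the score deterministic and exactly checkable against an
  independent tree-walking oracle.

The power-law fit is ordinary least squares of log₁₀ n(k) on log₁₀ k over
bins with k ≥ 1 and n(k) > 0 — the convention of the network-analysis tools
that report "y = a·x^b, R²" — not a maximum-likelihood exponent and not
nonlinear least squares. R² is reported on the log-log scale and defined as
1 for a numerically constant response (tolerance 1e-20 relative to Σy², a
pure floating-point guard). Noiseless data a·k^b is recovered to machine
precision, which is the basis of the acceptance check on the published
constants (a = 258.52, b = −1.171).

## Module detection

The detector reimplements the classical core-clustering algorithm: the
weight of a vertex is k_max × density of the highest k-core of the subgraph
induced by the vertex and its neighbours. Complexes grow breadth-first from
the highest-weight unvisited seed, admitting neighbours with weight ≥
seed_weight × (1 − node_score_cutoff); each node joins at most one complex.
Defaults (degree cutoff 2, node score cutoff 0.2, 2-core filter, haircut on,
fluff off, max depth 100) are the plugin defaults users will expect. All tie
breaks — seed order, expansion order — are lexicographic so output is a pure
function of the graph. Note the cutoff's direction: *raising*
node_score_cutoff lowers the admission threshold and can only enlarge a
complex; the property tests assert this monotonicity. A haircut can in
principle disconnect a complex; the seed's component is then kept.

## Enrichment and grouping

Term significance uses a two-sided hypergeometric test defined as the
doubled smaller tail, min(1, 2·min(P(X≥k), P(X≤k))), matching the
enrichment/depletion convention of pathway-grouping tools; one-sidedness is
recoverable by halving. The Bonferroni factor m is the number of *tested*
terms (k ≥ 1), switchable to all annotation terms. Grouping computes Cohen's
kappa between every pair of significant terms' query-hit membership vectors
over the universe and takes connected components at κ ≥ 0.4. Full iterative
leading-term merging (initial fixed-size groups, merged at ≥50% overlap)
would need parameters the use case does not constrain; components are
deterministic, parameter-light, and produce identical results whenever the
kappa graph's components are unambiguous. κ is defined as 1 when chance
agreement p_e = 1 and the sets are identical (both vectors constant).

## Prioritization cascade

"Top 10 bottleneck" keeps every node whose score falls in the ten largest
*distinct* score values — the only reading under which the published
22-protein candidate table is consistent with its "10 best scores" caption
(the table's distinct scores are 52, 22, 14, 13, 11, 10, 9, 7, 6, 5).
The date-hub filter is strict (< 0.5) on the clustering coefficient.
Pathway coverage counts groups whose associated genes contain the candidate;
candidates in no group count 0 and still enter the median. The cutoff is the
standard sample median (mean of the two middle values for even n) with ≥ at
the boundary — on the fixture, the even-n median is exactly 7 and the two
proteins at coverage 7 (CREB1, CASP8) are selected, which forces the ≥
choice.

### Transcribed tables

The 22-row candidate table pins bottleneck, clustering coefficient and
degree for every row, and betweenness/closeness only where the printed
(typographically run-together) numbers segment unambiguously; the remaining
cells are `None` and never asserted on. One protein is printed under two
aliases in the source tables (IL8/CXCL8); the fixture uses CXCL8 throughout
so names join across tables without an identifier-mapping service. The
cascade itself never reads the betweenness/closeness columns.

## Kinetics

Models are systems of mass-action reactions: integer stoichiometries, rate
kf·Πc_r (minus kr·Πc_p when reversible), concentrations in µM, time in
seconds. Integration uses LSODA with rtol 1e-8, atol 1e-10 and 1501 output
points over the horizon (defaults pinned for reproducibility); the t = 0
column is set to the initial condition exactly, and rate evaluation clips
concentrations at 0 so round-off excursions cannot feed negative fluxes.
Tightening tolerances tenfold moves 150 s readouts by far less than 1e-4 µM
(tested).

The built-in MAPK cascade is a reconstruction of the Huang–Ferrell (1996)
three-tier model from its published parameterization: every
(de)phosphorylation an explicit enzyme mechanism with association
1000 /(µM·s), dissociation 150 /s, catalysis 150 /s (Km = 0.3 µM
throughout); initial concentrations E1 3e-5, E2 3e-4, MAPKKK 3e-3,
MAPKK 1.2, MAPK 1.2, MAPKK-phosphatase 3e-4, MAPK-phosphatase 0.12 µM.
Simulating 150 s reproduces the canonical time course — free MAPK
1.19995 µM at 1.5 s and 0.0010782 µM at 150 s, doubly phosphorylated MAPK
0.981202 µM at 150 s — which both the tests and the acceptance script
recompute.

Inhibition is reversible sequestration: target + inhibitor ⇌ inert complex,
with the free inhibitor initialized at the dose (default 20 µM). The binding
constants are required arguments — no literature value constrains them — and
the examples use k_on = 1 /(µM·s) with k_off chosen so Kd = k_off/k_on =
0.66255 µM, echoing the reported docking Ki of 662.55 nM. By default only
free (unphosphorylated) MAPK is targeted; the spec of targets is a plain
tuple, so binding additional forms is a call-site choice. Because the
complex is inert and no other reaction touches the inhibitor, free + bound
inhibitor is an exact conservation law, verified to 1e-6 µM along the whole
trajectory. Simulated *inhibited* concentrations depend entirely on the
chosen k_on/k_off and are therefore illustrative, not reference values.

SBML support is deliberately a subset: level-2 documents whose kinetic laws
reduce, after parameter substitution, to the mass-action template implied by
the declared stoichiometries. The reader converts the MathML to a symbolic
polynomial and matches terms; anything else (Michaelis–Menten forms, rules,
events) is rejected with the reaction named, rather than silently misread.
Compartment sizes fold into the rate constants as ordinary parameters.

## Synthetic generators

All generators are bit-reproducible under a fixed seed (numpy Generator).

- *Scale-free*: preferential attachment pinned to a deterministic-edge-count
  variant — start from a star on m+1 nodes, each arrival attaches to m
  distinct degree-weighted targets — giving exactly (n−m)·m edges. It
  emulates the heavy-tailed degree structure of interactomes, not their
  clustering or community structure.
- *Random (Erdős–Rényi)*: the null model for the scale-free comparisons.
- *Planted modules*: disjoint cliques bridged into a sparse ER background by
  one edge each; clique size ≥ 5 on background density ≤ 0.05 is recovered
  at Jaccard ≥ 0.8 (acceptance check). Real complexes are denser-than-
  background but rarely perfect cliques, so recovery here bounds the easy
  case, not field performance.
- *Planted annotation*: a 1000-gene universe, 20 terms of 40 genes, a query
  of 25 genes of which 20 sit in the planted term — a strong signal whose
  detection probability across seeds (≥ 45/50) is a power check, not an
  estimate of power on real annotation structure (no term overlap
  correlation, no DAG).
- *Toy cascade*: a three-tier explicit-enzyme cascade with documented
  conserved moieties for conservation tests.

What passing these tests shows: the algorithms are implemented exactly (the
oracle checks are equality, not tolerance bands) and behave correctly on the
structures they were designed to find. What they do not show: that any
particular historical network's global statistics (node counts, module
counts, fitted exponents) are recovered — those depend on a specific
database retrieval and are out of scope.

## Problem sizes

Tests and the acceptance script run on deliberately small instances —
graphs of 10–600 nodes, universes of ≤ 1000 genes, 20-seed recovery
batteries, 150 s ODE horizons — chosen so the whole suite completes in
seconds while still exercising every code path and every exactness check at
full strictness.

## Known limitations

- Identifiers are opaque strings; no alias resolution or ID mapping.
- Enrichment has no GO-DAG awareness and no redundancy pruning beyond the
  kappa grouping.
- The SBML layer reads/writes only the mass-action subset described above.
- `InteractionNetwork.neighbors` is adjacency-on-demand (O(E)); the heavy
  algorithms convert to a networkx graph first, so this costs nothing in
  practice at the package's intended scales (≤ a few thousand nodes).
- Stochastic (SSA) simulation and parameter fitting are out of scope.
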