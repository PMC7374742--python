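# netpharm

Network-pharmacology analysis of drug-rewired protein-interaction networks
(PINs), built for the curcumin/MAPK use case but generic over any STRING-style
edge list. For systems biologists who want the classical inference chain —
interactome topology, dense-module detection, functional enrichment,
key-protein prioritization, and kinetic simulation of the downstream cascade —
as one tested, scriptable Python library.

## What it computes

**Topology.** Degree distribution with a log-log power-law fit
n(k) = a·k^b (OLS on log₁₀ scales, R² reported on the log-log scale),
clustering coefficients C(v) = 2e_v/(deg(v)(deg(v)−1)), characteristic path
length over reachable pairs, unnormalized shortest-path betweenness, harmonic
closeness Σ 1/d(v,u), and the **BottleNeck score**: for every root s, build
the BFS shortest-path tree T_s (lexicographic tie-breaks); node v earns one
point from s when more than |T_s|/4 of the tree's root-paths pass through v.

**Modules.** MCODE-style complex detection: vertex weight = k_max × density
of the highest k-core of the closed neighbourhood; seeded threshold expansion
(include a neighbour when its weight ≥ seed_weight·(1 − node_score_cutoff));
haircut / optional fluff post-processing; module score = density × size.

**Enrichment.** Two-sided hypergeometric test per term (doubled smaller tail,
capped at 1) with Bonferroni correction, then term grouping as connected
components of the Cohen-kappa graph (κ ≥ 0.4 between terms' gene-membership
vectors over the universe).

**Prioritization.** The key-protein cascade: keep nodes in the top-10
*distinct* bottleneck score levels → date-hub filter (clustering coefficient
< 0.5) → count enrichment groups covering each candidate → keep candidates at
or above the median coverage.

**Kinetics.** Mass-action ODE simulation (stiff LSODA, rtol 1e-8, atol
1e-10) of models loaded from SBML level-2 (mass-action subset) or a tiny text
dialect, including a built-in reconstruction of the Huang–Ferrell three-tier
MAPK cascade, plus reversible inhibitor injection (target + inhibitor ⇌ inert
complex) for dosing experiments such as 20 µM curcumin against MAPK1/Erk2.

## Worked example

```sh
python examples/04_key_protein_cascade.py
```

```
candidates after bottleneck + date-hub filters: 22
median pathway coverage (cutoff): 7
key proteins (12):
  MAPK1    covers 15 of 17 groups
  AKT1     covers 14 of 17 groups
  ...
  CREB1    covers  7 of 17 groups
```

Starting from the transcribed 22-protein candidate table (21 seed proteins
plus the connector RB1, all with clustering coefficient < 0.5, i.e. date
hubs), the cascade counts how many of the 17 functional groups each candidate
appears in, takes the median (7) as the cutoff, and returns the 12 key
regulators, led by MAPK1/Erk2 with 15 of 17 pathways.

```sh
python examples/05_mapk_kinetics_with_inhibitor.py
```

```
t=   0.0s  MAPK=1.2 µM        PP-MAPK=0 µM
t=   1.5s  MAPK=1.199954 µM   PP-MAPK=4.93e-10 µM
t= 150.0s  MAPK=0.0010782 µM  PP-MAPK=0.981202 µM
```

Over 150 s the cascade converts nearly the whole 1.2 µM MAPK pool into the
doubly phosphorylated active form; adding a 20 µM sequestering inhibitor
(Kd 662.55 nM) collapses activation to ~0.002 µM.

The other examples cover scale-free topology and power-law fitting (01),
planted-module recovery (02), and enrichment with kappa grouping (03). A thin
CLI mirrors the stages (`netpharm topology|modules|enrich|prioritize|kinetics|
fixtures|run`); `netpharm run --fixtures paper --out OUT` executes the
prioritization cascade end to end.

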