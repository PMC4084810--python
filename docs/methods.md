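# Methods

## Problem setting

A dynamic network is an ordered series of T ≥ 2 undirected, weighted
snapshots over a shared node universe. Nodes may be absent from individual
snapshots (a dropped vertex, not merely an isolated one — isolated present
vertices are retained, because network presence and community membership
are distinct concepts downstream). Time keys keep their input order: the
stitching stage is order-dependent by construction, so the analysis is only
meaningful in the order the data were sampled.

## Stage 1a: per-snapshot Louvain

Each snapshot is partitioned independently by the Louvain heuristic
(greedy local moves followed by graph aggregation, repeated until no move
improves Q), maximising Newman–Girvan modularity at resolution 1 with edge
weights honoured. Determinism is a hard requirement here — every
downstream product is a function of these partitions — so the node visit
order is drawn from a seeded generator after canonically sorting node
labels (input order is irrelevant), and a move is taken only when it
*strictly* improves Q (tolerance 1e-12): ties keep the node in its current
module. Isolated nodes form singleton groups, forced by the objective.
Edgeless snapshots get all-singleton partitions with modularity reported
as 0.0 (Q is undefined at zero total weight; the standalone `modularity`
function raises instead). An adapter (`partition_with`) accepts any
external node→group function for comparison or for injecting planted
partitions.

Louvain is a heuristic without optimality guarantees; the test suite pins
it to exhaustive modularity maximisation on the tiny graphs used there and
cross-checks the achieved Q against igraph's multilevel implementation.

## Stage 1b: Jaccard stitching

Groups of the first snapshot seed communities 1..G₁. For each later time
point t, groups search backwards: at each earlier time point (t−1, t−2, …,
at most `search_depth` steps, default unlimited) all pairs with Jaccard
index ≥ `jaccard_threshold` (default 0.4) are collected and assigned
greedily in descending Jaccard order, one-to-one in the earlier groups,
with ties broken by lower group id at t then lower earlier group id.
Groups that lose the one-to-one contest continue at deeper time points;
groups unmatched after the whole search found new communities in
(time, group id) order. Three deliberate choices:

* **One-to-one within a time point.** Without it, two groups at the same
  time could adopt the same community id and the per-time partition
  property — which the tabular reports and both stage-2 models assume —
  would be destroyed.
* **Zero overlap never matches**, even at threshold 0: "most similar"
  presupposes a shared member, and a J = 0 match would adopt an arbitrary
  label.
* **Recency first.** The search stops at the first earlier time point
  yielding an acceptable match rather than globally maximising J over all
  earlier times; within a time point the maximal J wins. This favours
  recent continuity over deep history.

Raising the threshold can only fragment communities; the sweep utilities
profile this (community count non-decreasing, mean community size
non-increasing, mean promiscuity non-decreasing on the benchmark
networks).

## Stage 2a: cost model

Per node, over home trajectories h₁..h_T drawn from the node's *observed*
communities, the model minimises

    Σ_{t≥2} switch_cost·[h_t ≠ h_{t−1}]
  + Σ_t    visit_cost ·[present(n,t) ∧ membership(n,t) ≠ h_t]
  + Σ_t    absence_cost·[absent(n,t) ∧ community_present(h_t, t)]

by dynamic programming over (time, candidate home). All three costs
default to 1 and must be nonnegative. Restricting candidates to observed
communities is lossless: an unobserved home can only add visit/absence
cost, and the tests confirm equality against enumeration over *all*
communities. Absence while the home community is itself absent costs
nothing (tag `exempt-absence`); homes are defined even at absent times
because the absence rule and the reports need them. Switch and visit are
independent indicators and may co-occur at one time step, so the itemised
accounting stores a tuple of event tags per (node, time).

Tie-breaking is canonical: states are ordered lexicographically by
(cost, number of switches), and remaining ties prefer the community the
node was observed in earliest — both for the final state and for each
predecessor choice — so equal-cost optima always resolve to the same
trajectory. Per-node DPs are independent because the objective is a sum of
per-node terms. The summary statistic is the average cost per node per
time step, C/(N·T).

## Stage 2b: sub-community model

Patterns are the full length-T trajectories including the ABSENT marker,
and grouping is exact equality: two nodes share a sub-community only if
they are also absent at the same times — synchronous presence is part of
"same dynamic behaviour". A constant pattern over the present times (e.g.
(1, ABSENT, 1)) shows no observed change and keeps its original community
label. New sub-community ids are issued above the community id range, in
order of each group's first member's node id. A node's "original
community" is its first observed community (for constant patterns this is
the constant; for variable ones the t=1 — or first present — value, a
documented convention since no single original exists).

Promiscuity is the number of community changes over consecutive time-point
pairs where the node is present at both, divided by T−1. Normalising by
T−1 (rather than by the number of comparable pairs) keeps the statistic
bounded in [0, 1] and comparable across nodes with different presence
patterns; a mostly-absent node cannot look maximally promiscuous from a
single observed change.

## Synthetic benchmark generator

A planted-partition (stochastic block model) generator: k communities of m
nodes, within-block edge probability `p_in`, between-block `p_out`
(defaults 0.95 / 0.02 over 4×12 nodes and T = 5 — well inside the
detectable regime for snapshots of this size, so stage-1 failures are
attributable to the algorithm, not the data), optional cohorts that move
between blocks in lockstep (ground-truth sub-communities), and per
(node, time) dropout that removes the vertex entirely. Recovery is scored
by the adjusted Rand index per time point, averaged.

What the generator does *not* emulate: heavy-tailed degree distributions,
overlapping modules, gradual community drift, weighted interaction
strengths, or correlated (non-independent) dropout of interacting nodes —
all features of real molecular or social data. Passing the planted-cohort
benchmarks therefore demonstrates the correctness of the pipeline's logic
under its own model assumptions, not performance on real networks.

## Input conventions

Dynamic GEXF: lifetimes may be spells, `start`/`end` attributes or single
timestamps; only numeric time formats are supported. The analysed
snapshots are taken at the sorted distinct start values (and timestamps)
in the file — the natural, deterministic discretisation when none is
prescribed — and intervals are closed-open, [start, end), so single-instant
membership is unambiguous; the edge-list reader is the escape hatch for
any other discretisation. An edge is included in a snapshot only while
both endpoints are alive, preserving the invariant that edge endpoints are
present. Self-loops and non-positive or non-finite weights are rejected at
load time in both readers.

## Reports and sweeps

CSV and HTML reports carry identical membership content (tested by parsing
both). Colours are assigned by a CRC32 hash of the community id into a
fixed 20-colour palette, so reports are reproducible run to run; distinct
ids can collide on colour, which is why every coloured box also shows the
id. Sweep statistics: community size counts distinct nodes ever assigned
to the community; sub-community count and mean size cover only the new
pattern-derived labels (constant-pattern nodes keep their original
community and unassigned nodes are excluded).

## Problem sizes

The bundled tests and the acceptance script run on small instances chosen
to make brute-force oracles feasible: exhaustive set-partition enumeration
up to 8 nodes, trajectory enumeration up to 5 communities × 6 time points,
planted networks of 48 nodes × 5 snapshots over 20 seeds. The pipeline
itself is not size-limited in this range; per-snapshot Louvain and the
per-node DP are near-linear in edges and candidate homes respectively.

## Known limitations

* Louvain resolution is fixed at 1; resolution-limit effects on large
  snapshots are not corrected.
* Matching is greedy and recency-first; it does not globally optimise a
  matching objective across all time points, and whether an earlier
  implementation enforced one-to-one matching within a time point is
  unknown — ours is a documented, test-pinned choice.
* Sub-community grouping is exact; near-miss patterns (one differing time
  point) are distinct labels by design.
* The cost model's tie-breaking among equal-cost trajectories is a
  canonical convention, not the only defensible one.
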