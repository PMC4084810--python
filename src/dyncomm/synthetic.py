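"""Synthetic dynamic networks with planted structure.

A planted-partition (stochastic block model style) generator for dynamic
networks: nodes carry a base community, optional *cohorts* of nodes move
between communities in lockstep (the ground-truth sub-communities), and
per-(node, time) dropout removes nodes from snapshots entirely, emulating
network absence.  Because block membership at every time is known exactly,
every pipeline stage can be scored against ground truth without any
external dataset.

The generator controls stability directly: with no cohorts and no dropout
the planted membership is constant over time (the regime the cost model
assumes), while cohorts create synchronized switching patterns (the regime
the sub-community model targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .network import ABSENT, DynamicNetwork


@dataclass
class Cohort:
    """A set of nodes that switch communities in lockstep.

    ``members`` are node ids of the generated network; ``targets`` gives
    the cohort's community at each of the T time points (ids in
    0..n_communities-1).
    """

    members: list[str]
    targets: list[int]


@dataclass
class SyntheticSpec:
    """Parameters of the planted dynamic network.

    Within-community edges appear with probability ``p_in``, between-
    community edges with ``p_out`` (< p_in).  ``p_absent`` is the per
    (node, time) dropout probability; a dropped node is removed from the
    snapshot entirely.  Node ids are ``n000, n001, ...`` with node i's base
    community ``i // nodes_per_community``.
    """

    n_communities: int = 4
    nodes_per_community: int = 12
    T: int = 5
    p_in: float = 0.95
    p_out: float = 0.02
    cohorts: list[Cohort] = field(default_factory=list)
    p_absent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        if self.nodes_per_community < 3:
            raise ValueError("need at least 3 nodes per community")
        if self.T < 2:
            raise ValueError("need at least 2 time points")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.p_absent < 1.0):
            raise ValueError("p_absent must be in [0, 1)")
        ids = set(self.node_ids())
        seen: set[str] = set()
        for co in self.cohorts:
            if len(co.targets) != self.T:
                raise ValueError("cohort targets must have length T")
            if any(not (0 <= c < self.n_communities) for c in co.targets):
                raise ValueError("cohort target community out of range")
            bad = set(co.members) - ids
            if bad:
                raise ValueError(f"cohort members not in network: {sorted(bad)}")
            if seen & set(co.members):
                raise ValueError("cohort node subsets must be disjoint")
            seen |= set(co.members)

    @property
    def n_nodes(self) -> int:
        return self.n_communities * self.nodes_per_community

    def node_ids(self) -> list[str]:
        return [f"n{i:03d}" for i in range(self.n_nodes)]


@dataclass
class GroundTruth:
    """Planted labels accompanying a generated network.

    ``membership`` is a node x time table of planted block ids (0-based),
    with :data:`ABSENT` where the node was dropped.  ``cohort_of`` maps
    each cohort member to its cohort's index.
    """

    membership: pd.DataFrame
    cohort_of: dict[str, int]

    def patterns(self) -> dict[str, tuple]:
        return {n: tuple(self.membership.loc[n]) for n in self.membership.index}


def generate(spec: SyntheticSpec) -> tuple[DynamicNetwork, GroundTruth]:
    """Draw one dynamic network from the planted model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    nodes = spec.node_ids()
    base = {n: i // spec.nodes_per_community for i, n in enumerate(nodes)}
    cohort_of: dict[str, int] = {}
    for ci, co in enumerate(spec.cohorts):
        for n in co.members:
            cohort_of[n] = ci

    times = list(range(1, spec.T + 1))
    snapshots: dict[Hashable, nx.Graph] = {}
    memb = pd.DataFrame(index=nodes, columns=times, dtype=object)
    for ti, t in enumerate(times):
        eff = {
            n: (spec.cohorts[cohort_of[n]].targets[ti] if n in cohort_of else base[n])
            for n in nodes
        }
        present = [n for n in nodes if rng.random() >= spec.p_absent]
        if not present:
            raise ValueError(f"snapshot at t={t} is empty; lower p_absent")
        g = nx.Graph(time=t)
        g.add_nodes_from(present)
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                u, v = present[i], present[j]
                p = spec.p_in if eff[u] == eff[v] else spec.p_out
                if rng.random() < p:
                    g.add_edge(u, v, weight=1.0)
        snapshots[t] = g
        present_set = set(present)
        for n in nodes:
            memb.loc[n, t] = eff[n] if n in present_set else ABSENT
    net = DynamicNetwork(times=times, snapshots=snapshots, node_ids=nodes)
    return net, GroundTruth(membership=memb, cohort_of=cohort_of)


def evaluate_recovery(
    inferred: Mapping[Hashable, Sequence] | pd.DataFrame,
    planted: Mapping[Hashable, Sequence] | pd.DataFrame,
) -> float:
    """Mean per-time adjusted Rand index between inferred and planted labels.

    Both arguments are node -> trajectory mappings (or node x time frames)
    over the same support: the same nodes must be marked ABSENT at the same
    times.  Returns the ARI averaged over time points; 1 exactly when the
    partitions agree (up to relabelling) at every time.
    """

    def as_map(x) -> dict:
        if isinstance(x, pd.DataFrame):
            return {n: tuple(x.loc[n]) for n in x.index}
        return {n: tuple(v) for n, v in x.items()}

    a, b = as_map(inferred), as_map(planted)
    if set(a) != set(b):
        raise ValueError("inferred and planted cover different node sets")
    nodes = sorted(a)
    T = len(a[nodes[0]])
    if any(len(a[n]) != T or len(b[n]) != T for n in nodes):
        raise ValueError("trajectory lengths differ")
    for n in nodes:
        if any((x == ABSENT) != (y == ABSENT) for x, y in zip(a[n], b[n])):
            raise ValueError(f"presence support differs for node {n!r}")
    scores = []
    for ti in range(T):
        lab_a = [a[n][ti] for n in nodes if a[n][ti] != ABSENT]
        lab_b = [b[n][ti] for n in nodes if b[n][ti] != ABSENT]
        scores.append(float(adjusted_rand_score(lab_b, lab_a)))
    return float(np.mean(scores))
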