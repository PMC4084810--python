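"""Stage 1a: independent partitioning of each snapshot into groups.

Each snapshot is partitioned by Louvain modularity optimisation, run
independently per time point.  A *group* is a module of one snapshot's
partition and exists only at that time; persistent *communities* are formed
later by stitching groups across time (see :mod:`dyncomm.matching`).

The Louvain implementation here is deliberately self-contained and fully
deterministic for a fixed seed: the node visit order is derived from the
seed (after canonically sorting node labels), never from input order, and
ties between equal-gain moves keep the node in its current module.  This
determinism is what makes the downstream stitching and trajectory models
testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .network import DynamicNetwork


def _canonical_order(nodes) -> list:
    """Stable, input-order-independent ordering of node labels."""
    return sorted(nodes, key=lambda n: (str(type(n).__name__), str(n)))


@dataclass
class GroupPartition:
    """Node -> group assignment for one snapshot.

    Group ids are dense integers ``0..G-1``, local to this time point.
    ``modularity`` is the Newman–Girvan modularity of this partition on this
    snapshot (0.0 by convention for snapshots with no edges, where Q is
    undefined).
    """

    time: Hashable
    groups: dict[int, set] = field(default_factory=dict)
    node_to_group: dict[Hashable, int] = field(default_factory=dict)
    modularity: float = 0.0

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def __post_init__(self) -> None:
        covered: set = set()
        for gid, members in self.groups.items():
            if covered & members:
                raise ValueError("groups overlap")
            covered |= members
        if covered != set(self.node_to_group):
            raise ValueError("groups and node_to_group disagree")
        if self.groups and sorted(self.groups) != list(range(len(self.groups))):
            raise ValueError("group ids must be 0..G-1 with no gaps")


def modularity(snapshot: nx.Graph, partition: Mapping[Hashable, int]) -> float:
    """Newman–Girvan modularity Q of ``partition`` on ``snapshot``.

    Q = sum_c [ w_in(c)/W - (d(c)/(2W))^2 ] with W the total edge weight,
    w_in(c) the weight inside module c and d(c) the total weighted degree of
    c.  Invariant to relabelling of the module ids.

    Raises
    ------
    ValueError
        If the partition does not cover every vertex, or the graph has zero
        total edge weight (Q undefined).
    """
    uncovered = [n for n in snapshot.nodes if n not in partition]
    if uncovered:
        raise ValueError(f"partition does not cover nodes {uncovered!r}")
    W = snapshot.size(weight="weight")
    if W <= 0:
        raise ValueError("modularity is undefined for a graph with zero total edge weight")
    w_in: dict[int, float] = {}
    degree: dict[int, float] = {}
    for n, d in snapshot.degree(weight="weight"):
        degree[partition[n]] = degree.get(partition[n], 0.0) + d
    for u, v, w in snapshot.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            w_in[partition[u]] = w_in.get(partition[u], 0.0) + w
    return sum(
        w_in.get(c, 0.0) / W - (degree[c] / (2.0 * W)) ** 2 for c in degree
    )


# ---------------------------------------------------------------------------
# Louvain


def _local_move(
    adj: dict[int, dict[int, float]],
    self_w: dict[int, float],
    order: list[int],
    W: float,
) -> dict[int, int]:
    """One Louvain level: greedy local moves until no move improves Q.

    ``adj`` is an adjacency map without self-loops; ``self_w`` carries the
    internal (self-loop) weight of each aggregated vertex.  Returns the
    vertex -> module map at this level.
    """
    comm = {n: n for n in adj}
    # community totals of weighted degree (self-loops count twice)
    k = {n: sum(adj[n].values()) + 2.0 * self_w.get(n, 0.0) for n in adj}
    tot = dict(k)
    improved = True
    while improved:
        improved = False
        for n in order:
            cn = comm[n]
            # weight from n to each neighbouring community
            links: dict[int, float] = {}
            for m, w in adj[n].items():
                links[comm[m]] = links.get(comm[m], 0.0) + w
            tot[cn] -= k[n]
            base = links.get(cn, 0.0) - k[n] * tot[cn] / (2.0 * W)
            best_c, best_gain = cn, base
            for c in sorted(links):
                if c == cn:
                    continue
                gain = links[c] - k[n] * tot[c] / (2.0 * W)
                # strict improvement required: ties keep the current module
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            tot[best_c] += k[n]
            if best_c != cn:
                comm[n] = best_c
                improved = True
    return comm


def _aggregate(
    adj: dict[int, dict[int, float]],
    self_w: dict[int, float],
    comm: dict[int, int],
) -> tuple[dict[int, dict[int, float]], dict[int, float], dict[int, int]]:
    """Condense modules into supervertices; returns (adj, self_w, relabel)."""
    labels = sorted(set(comm.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    new_adj: dict[int, dict[int, float]] = {i: {} for i in range(len(labels))}
    new_self: dict[int, float] = {i: 0.0 for i in range(len(labels))}
    for n, nbrs in adj.items():
        cn = relabel[comm[n]]
        new_self[cn] += self_w.get(n, 0.0)
        for m, w in nbrs.items():
            cm = relabel[comm[m]]
            if cn == cm:
                new_self[cn] += 0.5 * w  # each internal edge seen from both ends
            else:
                new_adj[cn][cm] = new_adj[cn].get(cm, 0.0) + w
    return new_adj, new_self, relabel


def louvain_partition(snapshot: nx.Graph, seed: int = 0) -> GroupPartition:
    """Partition one snapshot into groups by Louvain modularity optimisation.

    Deterministic for a fixed seed; the returned modularity is never below
    that of the all-singletons partition.  An empty snapshot yields an empty
    partition with 0 groups; an edgeless snapshot yields singleton groups
    (no merge can improve Q).
    """
    time = snapshot.graph.get("time")
    nodes = _canonical_order(snapshot.nodes)
    if not nodes:
        return GroupPartition(time=time, groups={}, node_to_group={}, modularity=0.0)
    W = snapshot.size(weight="weight")
    if W <= 0:
        groups = {i: {n} for i, n in enumerate(nodes)}
        n2g = {n: i for i, n in enumerate(nodes)}
        return GroupPartition(time=time, groups=groups, node_to_group=n2g, modularity=0.0)

    rng = np.random.default_rng(seed)
    index = {n: i for i, n in enumerate(nodes)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    for u, v, w in snapshot.edges(data="weight", default=1.0):
        iu, iv = index[u], index[v]
        adj[iu][iv] = adj[iu].get(iv, 0.0) + float(w)
        adj[iv][iu] = adj[iv].get(iu, 0.0) + float(w)
    self_w: dict[int, float] = {}

    # membership of the original vertices in the current level's vertices
    assign = {i: i for i in range(len(nodes))}
    while True:
        order = [int(i) for i in rng.permutation(sorted(adj))]
        comm = _local_move(adj, self_w, order, W)
        if all(comm[n] == n for n in adj) or len(set(comm.values())) == len(adj):
            break
        adj, self_w, relabel = _aggregate(adj, self_w, comm)
        assign = {n: relabel[comm[assign[n]]] for n in assign}
        if len(adj) == 1:
            break

    # dense group ids in canonical node order
    gid_of: dict[int, int] = {}
    node_to_group: dict[Hashable, int] = {}
    for n in nodes:
        c = assign[index[n]]
        if c not in gid_of:
            gid_of[c] = len(gid_of)
        node_to_group[n] = gid_of[c]
    groups: dict[int, set] = {}
    for n, g in node_to_group.items():
        groups.setdefault(g, set()).add(n)
    q = modularity(snapshot, node_to_group)
    return GroupPartition(time=time, groups=groups, node_to_group=node_to_group, modularity=q)


class LouvainPartitioner(BaseEstimator):
    """Per-snapshot Louvain partitioner (stage 1a).

    Parameters
    ----------
    random_state : int, default 0
        Seed controlling the node visit order; the same seed is used for
        every snapshot so partitioning at time t depends only on snapshot t.

    Attributes
    ----------
    partitions_ : list of GroupPartition
        One partition per time point, in time order.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X: DynamicNetwork, y=None) -> "LouvainPartitioner":
        if not isinstance(X, DynamicNetwork):
            raise TypeError("X must be a DynamicNetwork")
        parts = []
        for t in X.times:
            g = X.snapshots[t]
            p = louvain_partition(g, seed=self.random_state)
            p.time = t
            parts.append(p)
        self.partitions_ = parts
        return self

    def fit_transform(self, X: DynamicNetwork, y=None) -> list[GroupPartition]:
        return self.fit(X).partitions_

    transform = fit_transform


def partition_all(network: DynamicNetwork, seed: int = 0) -> list[GroupPartition]:
    """Partition every snapshot independently; list ordered by time."""
    return LouvainPartitioner(random_state=seed).fit_transform(network)


def partition_with(
    network: DynamicNetwork,
    partitioner: Callable[[nx.Graph], Mapping[Hashable, int]],
) -> list[GroupPartition]:
    """Adapter: build GroupPartitions from any external node->group function.

    Useful for comparing Louvain against another community detector or for
    injecting a planted partition in experiments.  Group labels returned by
    ``partitioner`` are re-encoded as dense ids 0..G-1 in canonical node
    order; modularity is recomputed (0.0 for edgeless snapshots).
    """
    parts = []
    for t in network.times:
        g = network.snapshots[t]
        raw = dict(partitioner(g))
        gid_of: dict = {}
        n2g: dict[Hashable, int] = {}
        for n in _canonical_order(g.nodes):
            lab = raw[n]
            if lab not in gid_of:
                gid_of[lab] = len(gid_of)
            n2g[n] = gid_of[lab]
        groups: dict[int, set] = {}
        for n, gid in n2g.items():
            groups.setdefault(gid, set()).add(n)
        q = modularity(g, n2g) if g.size(weight="weight") > 0 else 0.0
        parts.append(GroupPartition(time=t, groups=groups, node_to_group=n2g, modularity=q))
    return parts
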