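"""Stage 1b: stitching per-snapshot groups into persistent communities.

Groups found independently at each time point are assigned persistent
community identifiers by set overlap (Jaccard index) with groups at earlier
time points.  The groups of the first snapshot seed communities 1..G1.
Each later group searches backwards through time, one earlier time point at
a time, and adopts the community of its best acceptable match; a group with
no acceptable match anywhere within the search horizon founds a new
community.

Two rules the matching follows, both needed for well-defined output:

* matching within one earlier time point is one-to-one (two groups at time
  t may not claim the same earlier group in the same matched time point)
  and greedy in descending Jaccard order, so the per-time partition
  property survives stitching;
* a zero-overlap pair is never an acceptable match, whatever the threshold:
  "most similar" presupposes some shared member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

from sklearn.base import BaseEstimator

from .network import ABSENT
from .partition import GroupPartition


def jaccard(a: set, b: set) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two node sets.

    1 means the groups are identical; 0 means disjoint.  Undefined (raises)
    when both sets are empty.
    """
    if not a and not b:
        raise ValueError("Jaccard index is undefined for two empty sets")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


@dataclass
class MatchParameters:
    """User-facing knobs of the group-to-community matching.

    jaccard_threshold:
        Minimum Jaccard index for an acceptable match (default 0.4).
    search_depth:
        How many time points the backward search may step (1 = only t-1);
        ``None`` means unlimited, i.e. search back to the first snapshot.
    """

    jaccard_threshold: float = 0.4
    search_depth: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.jaccard_threshold <= 1.0) or not math.isfinite(
            self.jaccard_threshold
        ):
            raise ValueError(
                f"jaccard_threshold must be in [0, 1], got {self.jaccard_threshold!r}"
            )
        if self.search_depth is not None and self.search_depth < 1:
            raise ValueError("search_depth must be a positive integer or None")


@dataclass
class CommunityTimeline:
    """Group -> community identifiers across all time points.

    Community ids are global integers 1..n_communities, assigned in
    first-appearance order.  ``membership`` maps (node, time) to the
    community of the node's group at that time, or :data:`ABSENT`.
    """

    times: list[Hashable]
    nodes: list[Hashable]
    community_of_group: dict[tuple[Hashable, int], int]
    n_communities: int
    membership: dict[tuple[Hashable, Hashable], int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        used = set(self.community_of_group.values())
        if used and (min(used) < 1 or max(used) > self.n_communities):
            raise ValueError("community ids must lie in 1..n_communities")
        if len(used) != self.n_communities:
            raise ValueError("every community id 1..n_communities must be used")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def pattern(self, node: Hashable) -> tuple:
        """The node's full community trajectory (ABSENT where not present)."""
        return tuple(self.membership[(node, t)] for t in self.times)

    def communities_at(self, time: Hashable) -> set[int]:
        """Community ids with at least one group at ``time``."""
        return {
            c for (t, _g), c in self.community_of_group.items() if t == time
        }

    def members(self, community: int) -> set[Hashable]:
        """Nodes ever assigned to ``community``."""
        return {
            n
            for (n, _t), c in self.membership.items()
            if c == community
        }

    @classmethod
    def from_membership(
        cls,
        membership: dict[Hashable, Sequence],
        times: Sequence[Hashable] | None = None,
    ) -> "CommunityTimeline":
        """Build a timeline directly from per-node trajectories.

        ``membership`` maps each node to a length-T sequence of community
        ids (ints) and :data:`ABSENT` markers.  Every community present at a
        time is represented by one synthetic group, so the result behaves
        exactly like a stitched timeline; intended for tests and for running
        the stage-2 models on externally supplied membership tables.
        """
        nodes = list(membership)
        if not nodes:
            raise ValueError("membership is empty")
        T = len(membership[nodes[0]])
        if any(len(v) != T for v in membership.values()):
            raise ValueError("all trajectories must have the same length")
        tlist = list(times) if times is not None else list(range(1, T + 1))
        if len(tlist) != T:
            raise ValueError("times length does not match trajectory length")
        cids = sorted(
            {c for v in membership.values() for c in v if c != ABSENT}
        )
        if cids != list(range(1, len(cids) + 1)):
            remap = {c: i + 1 for i, c in enumerate(cids)}
        else:
            remap = {c: c for c in cids}
        cog: dict[tuple[Hashable, int], int] = {}
        memb: dict[tuple[Hashable, Hashable], int | str] = {}
        for ti, t in enumerate(tlist):
            present = sorted({remap[membership[n][ti]] for n in nodes if membership[n][ti] != ABSENT})
            for gid, c in enumerate(present):
                cog[(t, gid)] = c
            for n in nodes:
                v = membership[n][ti]
                memb[(n, t)] = ABSENT if v == ABSENT else remap[v]
        return cls(
            times=tlist,
            nodes=nodes,
            community_of_group=cog,
            n_communities=len(cids),
            membership=memb,
        )


def match_groups(
    partitions: Sequence[GroupPartition],
    params: MatchParameters | None = None,
) -> CommunityTimeline:
    """Assign every group a persistent community id by backward Jaccard search.

    The first snapshot's groups become communities 1..G1.  For each later
    time point t the candidate matches are evaluated one earlier time point
    at a time, starting at t-1: all acceptable (group, earlier-group) pairs
    at that time point — Jaccard >= threshold and > 0 — are assigned
    greedily in descending Jaccard order with one-to-one use of the earlier
    groups (ties broken by lower group id at t, then lower earlier group
    id).  Groups left unmatched continue the search at deeper time points,
    up to ``search_depth`` steps back; groups still unmatched afterwards
    found new communities in (time, group id) order.
    """
    params = params or MatchParameters()
    if not partitions:
        raise ValueError("no partitions given")
    times = [p.time for p in partitions]
    if len(set(times)) != len(times):
        raise ValueError(f"partition times overlap: {times!r}")

    cog: dict[tuple[Hashable, int], int] = {}
    next_cid = 1
    for gid in sorted(partitions[0].groups):
        cog[(times[0], gid)] = next_cid
        next_cid += 1

    max_depth = params.search_depth
    thr = params.jaccard_threshold
    for i in range(1, len(partitions)):
        part = partitions[i]
        remaining = set(part.groups)
        depth_limit = i if max_depth is None else min(max_depth, i)
        for depth in range(1, depth_limit + 1):
            if not remaining:
                break
            earlier = partitions[i - depth]
            pairs: list[tuple[float, int, int]] = []
            for g in sorted(remaining):
                for eg in sorted(earlier.groups):
                    j = jaccard(part.groups[g], earlier.groups[eg])
                    if j > 0.0 and j >= thr:
                        pairs.append((j, g, eg))
            pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
            used_earlier: set[int] = set()
            for j, g, eg in pairs:
                if g in remaining and eg not in used_earlier:
                    cog[(part.time, g)] = cog[(earlier.time, eg)]
                    remaining.discard(g)
                    used_earlier.add(eg)
        for g in sorted(remaining):
            cog[(part.time, g)] = next_cid
            next_cid += 1

    # node universe in first-appearance order over the partition series
    nodes: dict[Hashable, None] = {}
    for p in partitions:
        for n in p.node_to_group:
            nodes.setdefault(n)
    membership: dict[tuple[Hashable, Hashable], int | str] = {}
    for p in partitions:
        for n in nodes:
            g = p.node_to_group.get(n)
            membership[(n, p.time)] = ABSENT if g is None else cog[(p.time, g)]
    return CommunityTimeline(
        times=times,
        nodes=list(nodes),
        community_of_group=cog,
        n_communities=next_cid - 1,
        membership=membership,
    )


class GroupMatcher(BaseEstimator):
    """Stage-1b matcher as a scikit-learn style estimator.

    Parameters mirror :class:`MatchParameters`.  ``fit`` takes the list of
    per-snapshot :class:`GroupPartition` objects and exposes the stitched
    :class:`CommunityTimeline` as ``timeline_``.
    """

    def __init__(self, jaccard_threshold: float = 0.4, search_depth: int | None = None):
        self.jaccard_threshold = jaccard_threshold
        self.search_depth = search_depth

    def fit(self, X: Sequence[GroupPartition], y=None) -> "GroupMatcher":
        params = MatchParameters(
            jaccard_threshold=self.jaccard_threshold,
            search_depth=self.search_depth,
        )
        self.timeline_ = match_groups(list(X), params)
        self.n_communities_ = self.timeline_.n_communities
        return self

    def fit_transform(self, X: Sequence[GroupPartition], y=None) -> CommunityTimeline:
        return self.fit(X).timeline_

    transform = fit_transform
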