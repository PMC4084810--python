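"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: set
partitions are enumerated outright for modularity maximisation, node
trajectories are enumerated for the cost model, and group matching is
re-derived by repeated global argmax scans rather than the library's
sorted greedy pass.
"""

from __future__ import annotations

import itertools
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pytest

from dyncomm import ABSENT, CommunityTimeline, CostParameters, modularity
from dyncomm.matching import jaccard
from dyncomm.partition import GroupPartition


def graph_from_edges(edges, nodes=(), time=None) -> nx.Graph:
    g = nx.Graph(time=time)
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(e[0], e[1], weight=1.0)
    return g


# ---------------------------------------------------------------------------
# exhaustive modularity maximisation


def iter_set_partitions(items: list):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity_exhaustive(graph: nx.Graph) -> float:
    """Maximum Newman–Girvan modularity over every partition (<= 10 nodes)."""
    nodes = list(graph.nodes)
    assert len(nodes) <= 10, "exhaustive search only for tiny graphs"
    best = -np.inf
    for part in iter_set_partitions(nodes):
        assignment = {n: i for i, block in enumerate(part) for n in block}
        best = max(best, modularity(graph, assignment))
    return best


# ---------------------------------------------------------------------------
# exhaustive trajectory enumeration for the cost model


def min_cost_by_enumeration(
    trajectory: Sequence,
    candidates: Sequence[int],
    present_at: dict[Hashable, set[int]],
    times: Sequence[Hashable],
    params: CostParameters,
) -> float:
    """Minimal cost over all candidate home trajectories, by full enumeration."""
    best = np.inf
    for homes in itertools.product(candidates, repeat=len(times)):
        c = 0.0
        for ti, t in enumerate(times):
            if ti > 0 and homes[ti] != homes[ti - 1]:
                c += params.switch_cost
            m = trajectory[ti]
            if m != ABSENT:
                if m != homes[ti]:
                    c += params.visit_cost
            elif homes[ti] in present_at[t]:
                c += params.absence_cost
        best = min(best, c)
    return best


def random_timeline(
    rng: np.random.Generator,
    n_nodes: int,
    n_communities: int,
    n_times: int,
    p_absent: float = 0.2,
) -> CommunityTimeline:
    """Random membership matrix; every community used, every node seen once."""
    while True:
        memb = {}
        for i in range(n_nodes):
            traj = []
            for _t in range(n_times):
                if rng.random() < p_absent:
                    traj.append(ABSENT)
                else:
                    traj.append(int(rng.integers(1, n_communities + 1)))
            memb[f"v{i}"] = traj
        used = {c for v in memb.values() for c in v if c != ABSENT}
        if used and all(any(c != ABSENT for c in v) for v in memb.values()):
            return CommunityTimeline.from_membership(memb)


# ---------------------------------------------------------------------------
# independent reference matcher (repeated global argmax, no sorting pass)


def reference_match(
    partitions: Sequence[GroupPartition],
    threshold: float,
    search_depth: int | None = None,
) -> dict[tuple, int]:
    """(time, group) -> community mapping derived by repeated argmax scans."""
    times = [p.time for p in partitions]
    cog: dict[tuple, int] = {}
    next_cid = 1
    for gid in sorted(partitions[0].groups):
        cog[(times[0], gid)] = next_cid
        next_cid += 1
    for i in range(1, len(partitions)):
        part = partitions[i]
        remaining = set(part.groups)
        limit = i if search_depth is None else min(search_depth, i)
        for depth in range(1, limit + 1):
            if not remaining:
                break
            earlier = partitions[i - depth]
            used: set[int] = set()
            while True:
                best = None  # (J, g, eg) with J max, then g min, then eg min
                for g in sorted(remaining):
                    for eg in sorted(earlier.groups):
                        if eg in used:
                            continue
                        j = jaccard(part.groups[g], earlier.groups[eg])
                        if j <= 0.0 or j < threshold:
                            continue
                        if best is None or j > best[0] + 1e-12 or (
                            abs(j - best[0]) <= 1e-12 and (g, eg) < (best[1], best[2])
                        ):
                            best = (j, g, eg)
                if best is None:
                    break
                _j, g, eg = best
                cog[(part.time, g)] = cog[(earlier.time, eg)]
                remaining.discard(g)
                used.add(eg)
        for g in sorted(remaining):
            cog[(part.time, g)] = next_cid
            next_cid += 1
    return cog


def partitions_from_groups(groups_per_time: Sequence[Sequence[set]]) -> list[GroupPartition]:
    """Build GroupPartition objects straight from per-time lists of node sets."""
    parts = []
    for ti, groups in enumerate(groups_per_time, start=1):
        gmap = {i: set(g) for i, g in enumerate(groups)}
        n2g = {n: i for i, g in gmap.items() for n in g}
        parts.append(GroupPartition(time=ti, groups=gmap, node_to_group=n2g, modularity=0.0))
    return parts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
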