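"""Stage 2, option A: the home-community cost model.

Suited to networks whose communities are stable over time.  Each node is
assumed to have a 'home' community at every time point, and costs are
incurred when it *switches* home between consecutive time points, *visits*
a community other than its home (i.e. its group's community differs from
its home while present), or is *absent* from the network while its home
community is present.  Absence while the home community is itself absent
is exempt — the node cannot attend a community that is not there.

For each node independently the model picks, by dynamic programming over
(time, candidate home), the home trajectory minimising

    sum_{t>=2} switch_cost * [h_t != h_{t-1}]
  + sum_t     visit_cost  * [present(n,t) and membership(n,t) != h_t]
  + sum_t     absence_cost * [absent(n,t) and community_present(h_t, t)]

The candidate home set is the set of communities the node is ever observed
in: a home the node never visits is weakly dominated, since it can only
contribute visit and absence costs.  Ties between equal-cost trajectories
are broken towards fewer switches, then towards the community the node was
observed in earliest, giving one canonical assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from sklearn.base import BaseEstimator

from .matching import CommunityTimeline
from .network import ABSENT


@dataclass
class CostParameters:
    """Unit costs of the three penalised events (all default 1)."""

    switch_cost: float = 1.0
    visit_cost: float = 1.0
    absence_cost: float = 1.0

    def __post_init__(self) -> None:
        for name in ("switch_cost", "visit_cost", "absence_cost"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"{name} must be nonnegative, got {v!r}")


@dataclass
class HomeAssignment:
    """Per-node home-community trajectories with itemised cost accounting.

    ``itemised[(node, time)]`` is a tuple of event tags drawn from
    {'switch', 'visit', 'absence', 'exempt-absence'}; switch and visit can
    co-occur at one time step, the empty tuple means no event.  The
    invariant ``total_cost == sum(node_cost.values())`` equals the summed
    cost of all itemised events.
    """

    timeline: CommunityTimeline
    params: CostParameters
    home: dict[tuple[Hashable, Hashable], int] = field(default_factory=dict)
    node_cost: dict[Hashable, float] = field(default_factory=dict)
    itemised: dict[tuple[Hashable, Hashable], tuple[str, ...]] = field(default_factory=dict)
    total_cost: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.timeline.n_nodes

    @property
    def n_times(self) -> int:
        return self.timeline.n_times


def community_present(timeline: CommunityTimeline, community: int, time: Hashable) -> bool:
    """True iff at least one group at ``time`` belongs to ``community``."""
    if not (1 <= community <= timeline.n_communities):
        raise ValueError(f"unknown community id {community!r}")
    if time not in timeline.times:
        raise ValueError(f"unknown time key {time!r}")
    return any(
        c == community and t == time
        for (t, _g), c in timeline.community_of_group.items()
    )


def _present_sets(timeline: CommunityTimeline) -> dict[Hashable, set[int]]:
    out: dict[Hashable, set[int]] = {t: set() for t in timeline.times}
    for (t, _g), c in timeline.community_of_group.items():
        out[t].add(c)
    return out


def _assign_node(
    trajectory: tuple,
    candidates: list[int],
    present_at: dict[Hashable, set[int]],
    times: list[Hashable],
    p: CostParameters,
) -> tuple[list[int], float]:
    """DP over (time, candidate home) for one node.

    States are scored lexicographically by (cost, number of switches);
    ties beyond that are resolved by preferring candidates in the given
    order (earliest-observed first), both for the final state and for each
    predecessor choice.
    """
    T = len(times)

    def emission(ti: int, h: int) -> float:
        m = trajectory[ti]
        e = 0.0
        if m != ABSENT:
            if m != h:
                e += p.visit_cost
        elif h in present_at[times[ti]]:
            e += p.absence_cost
        return e

    # dp[h] = (cost, switches); back[ti][h] = chosen predecessor
    dp = {h: (emission(0, h), 0) for h in candidates}
    back: list[dict[int, int]] = []
    for ti in range(1, T):
        ndp: dict[int, tuple[float, int]] = {}
        bk: dict[int, int] = {}
        for h in candidates:
            best: tuple[float, int] | None = None
            best_hp = None
            for hp in candidates:
                c, s = dp[hp]
                if hp != h:
                    c, s = c + p.switch_cost, s + 1
                if best is None or (c, s) < best:
                    best, best_hp = (c, s), hp
            e = emission(ti, h)
            ndp[h] = (best[0] + e, best[1])
            bk[h] = best_hp
        dp = ndp
        back.append(bk)

    last = min(candidates, key=lambda h: dp[h])
    homes = [last]
    for bk in reversed(back):
        homes.append(bk[homes[-1]])
    homes.reverse()
    return homes, dp[last][0]


def assign_home(
    timeline: CommunityTimeline, params: CostParameters | None = None
) -> HomeAssignment:
    """Assign every node its cost-minimal home trajectory.

    Homes are defined at every time point, including times the node is
    absent (the absence rule needs them, and so do the tabular reports).
    Raises if some node is never observed in any community.
    """
    params = params or CostParameters()
    present_at = _present_sets(timeline)
    out = HomeAssignment(timeline=timeline, params=params)
    for n in timeline.nodes:
        traj = timeline.pattern(n)
        candidates: list[int] = []
        for c in traj:
            if c != ABSENT and c not in candidates:
                candidates.append(c)
        if not candidates:
            raise ValueError(f"node {n!r} is never a member of any community")
        homes, cost = _assign_node(traj, candidates, present_at, timeline.times, params)
        check = 0.0
        for ti, t in enumerate(timeline.times):
            h = homes[ti]
            out.home[(n, t)] = h
            tags: list[str] = []
            if ti > 0 and h != homes[ti - 1]:
                tags.append("switch")
                check += params.switch_cost
            if traj[ti] != ABSENT:
                if traj[ti] != h:
                    tags.append("visit")
                    check += params.visit_cost
            elif h in present_at[t]:
                tags.append("absence")
                check += params.absence_cost
            else:
                tags.append("exempt-absence")
            out.itemised[(n, t)] = tuple(tags)
        assert abs(check - cost) < 1e-9, "itemised events disagree with DP cost"
        out.node_cost[n] = cost
    out.total_cost = sum(out.node_cost.values())
    return out


def average_cost(assignment: HomeAssignment) -> float:
    """Average cost per node per time step, C / (N * T)."""
    return assignment.total_cost / (assignment.n_nodes * assignment.n_times)


class HomeCostModel(BaseEstimator):
    """Home-community cost model as a scikit-learn style estimator.

    ``fit`` takes a :class:`CommunityTimeline`; the fitted assignment is
    exposed as ``assignment_``, with ``total_cost_`` and ``average_cost_``
    convenience attributes.
    """

    def __init__(
        self,
        switch_cost: float = 1.0,
        visit_cost: float = 1.0,
        absence_cost: float = 1.0,
    ):
        self.switch_cost = switch_cost
        self.visit_cost = visit_cost
        self.absence_cost = absence_cost

    def fit(self, X: CommunityTimeline, y=None) -> "HomeCostModel":
        params = CostParameters(
            switch_cost=self.switch_cost,
            visit_cost=self.visit_cost,
            absence_cost=self.absence_cost,
        )
        self.assignment_ = assign_home(X, params)
        self.total_cost_ = self.assignment_.total_cost
        self.average_cost_ = average_cost(self.assignment_)
        return self

    def fit_transform(self, X: CommunityTimeline, y=None) -> HomeAssignment:
        return self.fit(X).assignment_

    transform = fit_transform
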