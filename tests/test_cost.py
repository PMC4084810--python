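"""Home-community cost model: DP optimality and cost accounting."""

import numpy as np
import pytest

from dyncomm import (
    ABSENT,
    CommunityTimeline,
    CostParameters,
    HomeCostModel,
    assign_home,
    average_cost,
    community_present,
)
from dyncomm.cost import _present_sets

from conftest import min_cost_by_enumeration, random_timeline


def timeline(memb, times=None):
    return CommunityTimeline.from_membership(memb, times=times)


def with_anchors(memb, communities, T):
    """Add one constant node per community so all communities are present."""
    out = dict(memb)
    for c in communities:
        out[f"_anchor{c}"] = [c] * T
    return out


class TestCommunityPresent:
    def test_presence_follows_groups(self):
        tl = timeline({"a": [1, 1], "b": [2, ABSENT]})
        assert community_present(tl, 1, 1) and community_present(tl, 1, 2)
        assert community_present(tl, 2, 1) and not community_present(tl, 2, 2)

    def test_unknown_community_is_an_error(self):
        tl = timeline({"a": [1, 1]})
        with pytest.raises(ValueError, match="unknown community"):
            community_present(tl, 99, 1)

    def test_unknown_time_is_an_error(self):
        tl = timeline({"a": [1, 1]})
        with pytest.raises(ValueError, match="time"):
            community_present(tl, 1, 99)


class TestAssignHome:
    def test_loyal_node_costs_nothing(self):
        tl = timeline({"a": [1, 1, 1], "b": [1, 1, 2]})
        a = assign_home(tl)
        assert a.node_cost["a"] == 0.0
        assert [a.home[("a", t)] for t in tl.times] == [1, 1, 1]
        assert all(a.itemised[("a", t)] == () for t in tl.times)

    def test_max_cost_over_six_steps_is_five(self):
        # a node in a different always-present community at each of 6 time
        # steps: the cheapest explanation under unit costs is cost 5
        memb = with_anchors({"x": [1, 2, 3, 4, 5, 6]}, range(1, 7), 6)
        a = assign_home(timeline(memb))
        assert a.node_cost["x"] == 5.0

    def test_single_excursion_is_a_visit_not_two_switches(self):
        # A at t=1,2,4 and B at t=3 with both communities always present:
        # home A throughout with one visit (cost 1) beats switching (cost 2)
        memb = with_anchors({"n": [1, 1, 2, 1]}, [1, 2], 4)
        a = assign_home(timeline(memb))
        assert a.node_cost["n"] == 1.0
        assert [a.home[("n", t)] for t in a.timeline.times] == [1, 1, 1, 1]
        assert a.itemised[("n", 3)] == ("visit",)

    def test_absence_exempt_when_home_community_absent(self):
        # community 2 exists only at t=1; node b absent at t=2 while its
        # home community is also absent: no cost at all
        tl = timeline({"a": [1, 1], "b": [2, ABSENT]})
        a = assign_home(tl)
        assert a.node_cost["b"] == 0.0
        assert a.itemised[("b", 2)] == ("exempt-absence",)

    def test_absence_costs_when_home_community_present(self):
        tl = timeline({"a": [1, 1, 1], "b": [1, ABSENT, 1]})
        a = assign_home(tl)
        assert a.node_cost["b"] == 1.0
        assert a.itemised[("b", 2)] == ("absence",)

    def test_node_never_in_any_community_is_an_error(self):
        tl = timeline({"a": [1, 1]})
        tl.nodes.append("ghost")
        tl.membership[("ghost", 1)] = ABSENT
        tl.membership[("ghost", 2)] = ABSENT
        with pytest.raises(ValueError, match="ghost"):
            assign_home(tl)

    def test_total_cost_matches_itemised_events(self, rng):
        p = CostParameters(switch_cost=2.0, visit_cost=0.5, absence_cost=1.5)
        tl = random_timeline(rng, n_nodes=8, n_communities=4, n_times=5)
        a = assign_home(tl, p)
        total = 0.0
        for (n, t), tags in a.itemised.items():
            for tag in tags:
                total += {"switch": 2.0, "visit": 0.5, "absence": 1.5,
                          "exempt-absence": 0.0}[tag]
        assert a.total_cost == pytest.approx(total)
        assert a.total_cost == pytest.approx(sum(a.node_cost.values()))

    @pytest.mark.parametrize("costs", [
        CostParameters(),
        CostParameters(switch_cost=2.0, visit_cost=0.7, absence_cost=0.3),
        CostParameters(switch_cost=0.0, visit_cost=1.0, absence_cost=1.0),
    ])
    def test_dp_equals_exhaustive_enumeration(self, rng, costs):
        for _ in range(40):
            tl = random_timeline(
                rng,
                n_nodes=4,
                n_communities=int(rng.integers(2, 6)),
                n_times=int(rng.integers(2, 7)),
            )
            a = assign_home(tl, costs)
            present_at = _present_sets(tl)
            for n in tl.nodes:
                traj = tl.pattern(n)
                cands = sorted({c for c in traj if c != ABSENT})
                expected = min_cost_by_enumeration(traj, cands, present_at, tl.times, costs)
                assert a.node_cost[n] == pytest.approx(expected), (n, traj)

    def test_scaling_all_costs_scales_every_node_cost(self, rng):
        tl = random_timeline(rng, n_nodes=6, n_communities=3, n_times=5)
        a1 = assign_home(tl, CostParameters(1.0, 1.0, 1.0))
        a3 = assign_home(tl, CostParameters(3.0, 3.0, 3.0))
        for n in tl.nodes:
            assert a3.node_cost[n] == pytest.approx(3.0 * a1.node_cost[n])
        assert a3.home == a1.home  # argmin trajectory set unchanged

    def test_zero_absence_cost_ignores_presence_pattern(self, rng):
        # with absence_cost = 0 an absent step is free and unconstrained, so
        # the cost must equal that of the trajectory with absences dropped
        tl = random_timeline(rng, n_nodes=8, n_communities=3, n_times=6, p_absent=0.4)
        p = CostParameters(absence_cost=0.0)
        a = assign_home(tl, p)
        for n in tl.nodes:
            traj = [c for c in tl.pattern(n) if c != ABSENT]
            times = list(range(len(traj)))
            cands = sorted(set(traj))
            present_at = {t: set(cands) for t in times}
            expected = min_cost_by_enumeration(traj, cands, present_at, times, p)
            assert a.node_cost[n] == pytest.approx(expected)

    def test_deterministic_reruns(self, rng):
        tl = random_timeline(rng, n_nodes=10, n_communities=4, n_times=6)
        a1, a2 = assign_home(tl), assign_home(tl)
        assert a1.home == a2.home and a1.node_cost == a2.node_cost

    def test_candidate_restriction_matches_all_community_candidates(self, rng):
        # homes outside the observed set are weakly dominated: allowing
        # every community as a candidate never achieves a lower cost
        for _ in range(20):
            tl = random_timeline(rng, n_nodes=3, n_communities=4, n_times=4)
            a = assign_home(tl)
            present_at = _present_sets(tl)
            all_comms = list(range(1, tl.n_communities + 1))
            for n in tl.nodes:
                traj = tl.pattern(n)
                full = min_cost_by_enumeration(
                    traj, all_comms, present_at, tl.times, CostParameters()
                )
                assert a.node_cost[n] == pytest.approx(full)


class TestAverageCost:
    def test_printed_summary_value(self):
        tl = timeline({"a": [1, 1]})
        a = assign_home(tl)
        a.node_cost = {"a": 37.0}
        a.total_cost = 37.0
        object.__setattr__(a.timeline, "nodes", [f"w{i}" for i in range(18)])
        object.__setattr__(a.timeline, "times", list(range(14)))
        assert round(average_cost(a), 3) == 0.147

    def test_plain_arithmetic(self):
        tl = timeline({"a": [1, 1]})
        a = assign_home(tl)
        a.total_cost = 12.0
        object.__setattr__(a.timeline, "nodes", list("wxyz"))
        object.__setattr__(a.timeline, "times", list(range(6)))
        assert average_cost(a) == 0.5

    def test_zero_cost_assignment(self):
        a = assign_home(timeline({"a": [1, 1]}))
        assert average_cost(a) == 0.0


def test_estimator_wrapper(rng):
    from sklearn.base import clone

    tl = random_timeline(rng, n_nodes=5, n_communities=3, n_times=4)
    est = HomeCostModel(switch_cost=2.0)
    assert clone(est).get_params()["switch_cost"] == 2.0
    est.fit(tl)
    assert est.total_cost_ == est.assignment_.total_cost
    assert est.average_cost_ == pytest.approx(
        est.total_cost_ / (tl.n_nodes * tl.n_times)
    )
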