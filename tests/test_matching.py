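"""Stage-1b stitching: Jaccard index and group-to-community matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyncomm import ABSENT, MatchParameters, jaccard, match_groups

from conftest import partitions_from_groups, reference_match

sets = st.sets(st.integers(0, 12), min_size=0, max_size=8)


class TestJaccard:
    def test_identical_groups_score_one(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_groups_score_zero(self):
        assert jaccard({1, 2}, {3}) == 0.0

    def test_half_overlap(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard(set(), set())

    @settings(derandomize=True, max_examples=60)
    @given(a=sets, b=sets)
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)


class TestMatchParameters:
    @pytest.mark.parametrize("thr", [-0.1, 1.5, float("nan")])
    def test_threshold_out_of_range_rejected(self, thr):
        with pytest.raises(ValueError):
            MatchParameters(jaccard_threshold=thr)

    def test_search_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            MatchParameters(search_depth=0)


class TestMatchGroups:
    def test_identical_partitions_inherit_all_communities(self):
        parts = partitions_from_groups(
            [[{"a", "b", "c"}, {"d", "e"}], [{"a", "b", "c"}, {"d", "e"}]]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4))
        assert tl.n_communities == 2
        assert tl.pattern("a") == (1, 1) and tl.pattern("d") == (2, 2)

    def test_partial_overlap_matches_and_disjoint_founds_new(self):
        # {a,b,x} vs {a,b,c}: J = 2/4 = 0.5 >= 0.4 -> inherit community 1;
        # {y,z} is disjoint from everything -> new community 3
        parts = partitions_from_groups(
            [[{"a", "b", "c"}, {"d", "e"}], [{"a", "b", "x"}, {"y", "z"}]]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4))
        assert tl.n_communities == 3
        assert tl.membership[("a", 2)] == 1
        assert tl.membership[("y", 2)] == 3

    def test_lookback_past_immediate_predecessor(self):
        # at t=3 the group equals a t=1 group, while nothing at t=2 reaches
        # the threshold: the community must come from t=1
        parts = partitions_from_groups(
            [
                [{"a", "b", "c"}],
                [{"p", "q", "r"}],
                [{"a", "b", "c"}],
            ]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4))
        assert tl.membership[("a", 3)] == 1
        assert tl.n_communities == 2

    def test_search_depth_one_blocks_deep_lookback(self):
        parts = partitions_from_groups(
            [[{"a", "b", "c"}], [{"p", "q", "r"}], [{"a", "b", "c"}]]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4, search_depth=1))
        assert tl.membership[("a", 3)] == 3  # fresh community, t=1 unreachable
        assert tl.n_communities == 3

    def test_threshold_above_any_achievable_match_fragments_everything(self):
        parts = partitions_from_groups(
            [[{"a", "b"}, {"c"}], [{"a", "c"}, {"b"}], [{"a"}, {"b", "c"}]]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=1.0))
        assert tl.n_communities == sum(len(p.groups) for p in parts)

    def test_zero_overlap_never_matches_even_at_threshold_zero(self):
        parts = partitions_from_groups([[{"a", "b"}], [{"x", "y"}]])
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.0))
        assert tl.n_communities == 2

    def test_one_to_one_within_a_time_point(self):
        # both t=2 groups overlap the same t=1 group best; only one may
        # take its community, the other must fall back to a new one
        parts = partitions_from_groups(
            [[{"a", "b", "c", "d"}], [{"a", "b"}, {"c", "d"}]]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.3))
        got = {tl.community_of_group[(2, 0)], tl.community_of_group[(2, 1)]}
        assert got == {1, 2}

    def test_unmatched_after_greedy_continues_deeper(self):
        # t=3 group {c,d} loses the one-to-one contest at t=2 (both t=3
        # groups tie at J=0.5; the lower group id wins) but finds its twin
        # at t=1, so it keeps that community instead of founding one
        parts = partitions_from_groups(
            [
                [{"a", "b"}, {"c", "d"}],
                [{"a", "b", "c", "d"}],
                [{"a", "b"}, {"c", "d"}],
            ]
        )
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4))
        assert tl.community_of_group[(3, 0)] == 1
        assert tl.community_of_group[(3, 1)] == 2
        assert tl.n_communities == 2

    def test_overlapping_times_rejected(self):
        parts = partitions_from_groups([[{"a"}], [{"a"}]])
        parts[1].time = parts[0].time
        with pytest.raises(ValueError, match="overlap"):
            match_groups(parts)

    def test_absent_nodes_marked_absent(self):
        parts = partitions_from_groups([[{"a", "b"}], [{"a"}]])
        tl = match_groups(parts, MatchParameters(jaccard_threshold=0.4))
        assert tl.membership[("b", 2)] == ABSENT

    @pytest.mark.parametrize("threshold", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("depth", [None, 1, 2])
    def test_equivalence_with_reference_matcher(self, rng, threshold, depth):
        for _ in range(30):
            T = int(rng.integers(2, 5))
            universe = [f"v{i}" for i in range(8)]
            per_time = []
            for _t in range(T):
                present = [n for n in universe if rng.random() < 0.8] or [universe[0]]
                k = int(rng.integers(1, min(4, len(present)) + 1))
                labels = rng.integers(0, k, size=len(present))
                groups = {}
                for n, l in zip(present, labels):
                    groups.setdefault(int(l), set()).add(n)
                per_time.append(list(groups.values()))
            parts = partitions_from_groups(per_time)
            tl = match_groups(
                parts, MatchParameters(jaccard_threshold=threshold, search_depth=depth)
            )
            assert tl.community_of_group == reference_match(parts, threshold, depth)

    def test_raising_threshold_never_merges_communities(self, rng):
        for _ in range(10):
            per_time = []
            for _t in range(4):
                present = [f"v{i}" for i in range(10) if rng.random() < 0.85]
                if not present:
                    present = ["v0"]
                k = int(rng.integers(1, 4))
                labels = rng.integers(0, k, size=len(present))
                groups = {}
                for n, l in zip(present, labels):
                    groups.setdefault(int(l), set()).add(n)
                per_time.append(list(groups.values()))
            parts = partitions_from_groups(per_time)
            counts = [
                match_groups(parts, MatchParameters(jaccard_threshold=th)).n_communities
                for th in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
            ]
            assert counts == sorted(counts)
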