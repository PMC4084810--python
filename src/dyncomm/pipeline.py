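"""End-to-end pipeline: partition -> match -> stage-2 model.

:class:`DynamicCommunityDetector` is the one-stop estimator; it runs
per-snapshot Louvain, Jaccard stitching and the chosen stage-2 model in
one ``fit`` and exposes every intermediate product as a fitted attribute.
``sweep_thresholds`` reuses stage-1 partitions (which do not depend on the
matching threshold) to profile how community statistics respond to the
Jaccard acceptance threshold.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cost import HomeCostModel
from .matching import CommunityTimeline, GroupMatcher
from .network import DynamicNetwork
from .partition import GroupPartition, LouvainPartitioner
from .subcommunity import SubCommunityModel


class DynamicCommunityDetector(BaseEstimator):
    """Full dynamic community detection pipeline.

    Parameters
    ----------
    model : {'subcommunity', 'cost'}
        Stage-2 model: sub-community pattern grouping (for unstable
        community structure) or the home-community cost model (for stable
        structure).
    jaccard_threshold : float, default 0.4
        Minimum Jaccard index for stitching a group to an earlier one.
    search_depth : int or None, default None
        Backward search horizon in time points (None = unlimited).
    switch_cost, visit_cost, absence_cost : float, default 1
        Cost-model event costs (ignored by the sub-community model).
    random_state : int, default 0
        Seed for the Louvain node visit order.

    Attributes
    ----------
    partitions_ : list of GroupPartition
    timeline_ : CommunityTimeline
    n_communities_ : int
    result_ : HomeAssignment or SubCommunityAssignment
    membership_ : pandas.DataFrame
        Node x time community table (ABSENT marker where absent).
    """

    def __init__(
        self,
        model: str = "subcommunity",
        jaccard_threshold: float = 0.4,
        search_depth: int | None = None,
        switch_cost: float = 1.0,
        visit_cost: float = 1.0,
        absence_cost: float = 1.0,
        random_state: int = 0,
    ):
        self.model = model
        self.jaccard_threshold = jaccard_threshold
        self.search_depth = search_depth
        self.switch_cost = switch_cost
        self.visit_cost = visit_cost
        self.absence_cost = absence_cost
        self.random_state = random_state

    def fit(self, X: DynamicNetwork, y=None) -> "DynamicCommunityDetector":
        if self.model not in ("subcommunity", "cost"):
            raise ValueError(f"unknown model {self.model!r}")
        self.partitions_ = LouvainPartitioner(
            random_state=self.random_state
        ).fit_transform(X)
        self.timeline_ = GroupMatcher(
            jaccard_threshold=self.jaccard_threshold,
            search_depth=self.search_depth,
        ).fit_transform(self.partitions_)
        self.n_communities_ = self.timeline_.n_communities
        if self.model == "cost":
            m = HomeCostModel(
                switch_cost=self.switch_cost,
                visit_cost=self.visit_cost,
                absence_cost=self.absence_cost,
            ).fit(self.timeline_)
            self.result_ = m.assignment_
            self.total_cost_ = m.total_cost_
            self.average_cost_ = m.average_cost_
        else:
            m = SubCommunityModel().fit(self.timeline_)
            self.result_ = m.assignment_
            self.n_subcommunities_ = m.n_subcommunities_
        self.membership_ = pd.DataFrame(
            {
                t: [self.timeline_.membership[(n, t)] for n in self.timeline_.nodes]
                for t in self.timeline_.times
            },
            index=self.timeline_.nodes,
        )
        return self


def timeline_statistics(timeline: CommunityTimeline) -> dict[str, float]:
    """Community / sub-community summary statistics for one timeline.

    Community size counts the distinct nodes ever assigned to a community;
    sub-community counts and sizes cover only the new pattern-derived
    labels (constant-pattern nodes keep their original community and are
    not counted as sub-communities).
    """
    sub = SubCommunityModel().fit(timeline).assignment_
    comm_sizes = [len(timeline.members(c)) for c in range(1, timeline.n_communities + 1)]
    new_sizes = [
        cnt
        for lab, cnt in sub.sizes.items()
        if isinstance(lab, int) and lab > timeline.n_communities
    ]
    return {
        "n_communities": timeline.n_communities,
        "mean_community_size": float(np.mean(comm_sizes)),
        "n_subcommunities": len(new_sizes),
        "mean_subcommunity_size": float(np.mean(new_sizes)) if new_sizes else 0.0,
        "mean_node_promiscuity": float(np.mean(list(sub.promiscuity.values()))),
    }


def sweep_thresholds(
    partitions: Sequence[GroupPartition],
    thresholds: Sequence[float],
    search_depth: int | None = None,
) -> pd.DataFrame:
    """Match the same stage-1 partitions at each threshold; one row per value.

    Stage-1 partitioning does not depend on the matching threshold, so the
    partitions are computed once by the caller and re-matched here.
    Thresholds must be sorted ascending.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if any(not (0.0 <= th <= 1.0) for th in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for th in thresholds:
        timeline = GroupMatcher(
            jaccard_threshold=th, search_depth=search_depth
        ).fit_transform(partitions)
        rows.append({"threshold": th, **timeline_statistics(timeline)})
    return pd.DataFrame(rows)
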