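"""Stage 2, option B: the sub-community pattern model.

Suited to networks whose community structure cannot be assumed stable
(time-course molecular interaction data, for instance).  Every node simply
belongs to its group's community at each time point — no costs, no notion
of visiting — and the model instead looks for sets of nodes whose full
community-membership trajectories are *identical*, absences included.
Such a set is a new *sub-community*: its members change communities, but
always together.

Labelling rules:

* a node whose trajectory is constant over the times it is present keeps
  its original community as its label (no community change was ever
  observed, even if the node was sometimes absent);
* nodes sharing a non-constant trajectory with at least one other node form
  a sub-community, labelled with a fresh integer above the community id
  range;
* a node with a unique non-constant trajectory is left unassigned.

The model also computes each node's *promiscuity*: the frequency with
which it changes community affiliation, counted over consecutive time
point pairs where the node is present at both and normalised by T - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .matching import CommunityTimeline
from .network import ABSENT
from .partition import _canonical_order

#: Label for nodes with a unique, non-constant membership pattern.
UNASSIGNED = "unassigned"


@dataclass
class SubCommunityAssignment:
    """Sub-community labels, sizes and promiscuity per node.

    ``label`` maps each node to a sub-community id (a fresh integer above
    the community range), its original community id (constant pattern), or
    :data:`UNASSIGNED`.  ``original`` records the node's first observed
    community.  ``sizes`` counts members per label, including the
    UNASSIGNED pool.
    """

    timeline: CommunityTimeline
    pattern: dict[Hashable, tuple] = field(default_factory=dict)
    label: dict[Hashable, int | str] = field(default_factory=dict)
    original: dict[Hashable, int] = field(default_factory=dict)
    sizes: dict[int | str, int] = field(default_factory=dict)
    promiscuity: dict[Hashable, float] = field(default_factory=dict)

    @property
    def n_subcommunities(self) -> int:
        """Number of new (pattern-derived) sub-communities."""
        return len(
            {
                l
                for l in self.label.values()
                if isinstance(l, int) and l > self.timeline.n_communities
            }
        )


def membership_patterns(timeline: CommunityTimeline) -> dict[Hashable, tuple]:
    """Full membership trajectory per node, length T, ABSENT where absent."""
    return {n: timeline.pattern(n) for n in timeline.nodes}


def node_promiscuity(pattern: Sequence) -> float:
    """Fraction of consecutive present-present time pairs with a community change.

    Transitions into or out of absence do not count as changes; the
    denominator is T - 1 so values are comparable across nodes and bounded
    in [0, 1].
    """
    if len(pattern) < 2:
        raise ValueError("promiscuity needs at least 2 time points")
    changes = sum(
        1
        for a, b in zip(pattern, pattern[1:])
        if a != ABSENT and b != ABSENT and a != b
    )
    return changes / (len(pattern) - 1)


def _is_constant(pattern: Sequence) -> bool:
    seen = {c for c in pattern if c != ABSENT}
    return len(seen) <= 1


def derive_subcommunities(
    patterns: Mapping[Hashable, tuple],
    timeline: CommunityTimeline | None = None,
) -> SubCommunityAssignment:
    """Group nodes by exact trajectory equality into sub-communities.

    Equality is over the full vector: two nodes must be absent at the same
    times to share a sub-community.  New sub-community ids start above the
    community id range and are issued in order of each pattern group's
    first member's node id.
    """
    if timeline is None:
        timeline = CommunityTimeline.from_membership(
            {n: list(p) for n, p in patterns.items()}
        )
    out = SubCommunityAssignment(timeline=timeline)
    out.pattern = {n: tuple(p) for n, p in patterns.items()}

    by_pattern: dict[tuple, list[Hashable]] = {}
    for n in out.pattern:
        by_pattern.setdefault(out.pattern[n], []).append(n)

    # fresh ids above the community range, ordered by first member's node id
    shared_nonconstant = [
        pat for pat, members in by_pattern.items()
        if len(members) > 1 and not _is_constant(pat)
    ]
    shared_nonconstant.sort(
        key=lambda pat: str(_canonical_order(by_pattern[pat])[0])
    )
    next_id = timeline.n_communities + 1
    sub_id: dict[tuple, int] = {}
    for pat in shared_nonconstant:
        sub_id[pat] = next_id
        next_id += 1

    for n, pat in out.pattern.items():
        present = [c for c in pat if c != ABSENT]
        if not present:
            raise ValueError(f"node {n!r} has an all-absent pattern")
        out.original[n] = present[0]
        if _is_constant(pat):
            out.label[n] = present[0]
        elif pat in sub_id:
            out.label[n] = sub_id[pat]
        else:
            out.label[n] = UNASSIGNED
        out.promiscuity[n] = node_promiscuity(pat)

    for n, lab in out.label.items():
        out.sizes[lab] = out.sizes.get(lab, 0) + 1
    return out


class SubCommunityModel(BaseEstimator):
    """Sub-community pattern model as a scikit-learn style estimator.

    ``fit`` takes a :class:`CommunityTimeline`; the fitted
    :class:`SubCommunityAssignment` is exposed as ``assignment_`` with
    ``n_subcommunities_`` as a convenience attribute.
    """

    def fit(self, X: CommunityTimeline, y=None) -> "SubCommunityModel":
        patterns = membership_patterns(X)
        self.assignment_ = derive_subcommunities(patterns, timeline=X)
        self.n_subcommunities_ = self.assignment_.n_subcommunities
        return self

    def fit_transform(self, X: CommunityTimeline, y=None) -> SubCommunityAssignment:
        return self.fit(X).assignment_

    transform = fit_transform
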