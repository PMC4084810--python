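"""Core container for dynamic networks.

A dynamic network is an ordered series of undirected, weighted network
snapshots over a shared node universe.  A node is *present* at a time point
exactly when it appears as a vertex of that snapshot (isolated vertices
count as present: presence in the network is distinct from membership in
any community).  Time keys keep their input order — community stitching
depends on the order in which snapshots were sampled, so reordering them
changes the meaning of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Placeholder used in membership trajectories and reports for time points at
#: which a node is not part of the snapshot.
ABSENT = "-"


class DynamicNetworkError(ValueError):
    """Raised when a dynamic network violates its structural invariants."""


@dataclass
class DynamicNetwork:
    """An ordered series of network snapshots.

    Parameters
    ----------
    times:
        Ordered list of at least two distinct time keys.  The order given
        here is the analysis order.
    snapshots:
        One undirected :class:`networkx.Graph` per time key.  Vertices of
        snapshot ``t`` are the nodes present at ``t``.  Edge weights default
        to 1 and must be finite and strictly positive; self-loops are
        rejected.
    node_ids:
        Ordered node universe.  Derived (first-appearance order over the
        time series) when not given.
    """

    times: list[Hashable]
    snapshots: dict[Hashable, nx.Graph]
    node_ids: list[Hashable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) < 2:
            raise DynamicNetworkError(
                f"a dynamic network needs at least 2 time points, got {len(self.times)}"
            )
        if len(set(self.times)) != len(self.times):
            raise DynamicNetworkError("time keys must be distinct")
        missing = [t for t in self.times if t not in self.snapshots]
        if missing:
            raise DynamicNetworkError(f"no snapshot for time keys {missing!r}")
        for t in self.times:
            g = self.snapshots[t]
            if g.is_directed():
                raise DynamicNetworkError(f"snapshot at {t!r} is directed")
            for u, v, data in g.edges(data=True):
                if u == v:
                    raise DynamicNetworkError(
                        f"self-loop on node {u!r} in snapshot at time {t!r}"
                    )
                w = data.get("weight", 1.0)
                if not (isinstance(w, (int, float)) and math.isfinite(w) and w > 0):
                    raise DynamicNetworkError(
                        f"edge ({u!r}, {v!r}) at time {t!r} has invalid weight {w!r}; "
                        "weights must be finite and > 0"
                    )
                data.setdefault("weight", 1.0)
        if not self.node_ids:
            seen: dict[Hashable, None] = {}
            for t in self.times:
                for n in self.snapshots[t].nodes:
                    seen.setdefault(n)
            self.node_ids = list(seen)
        else:
            universe = set(self.node_ids)
            for t in self.times:
                extra = set(self.snapshots[t].nodes) - universe
                if extra:
                    raise DynamicNetworkError(
                        f"snapshot at {t!r} contains nodes outside the universe: {sorted(map(str, extra))}"
                    )

    # -- presence ---------------------------------------------------------

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def present(self, node: Hashable, time: Hashable) -> bool:
        """True iff ``node`` is a vertex of the snapshot at ``time``."""
        return self.snapshots[time].has_node(node)

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean node x time presence table (rows in node order)."""
        data = {
            t: [self.present(n, t) for n in self.node_ids] for t in self.times
        }
        return pd.DataFrame(data, index=self.node_ids, columns=self.times)

    @classmethod
    def from_snapshots(
        cls,
        snapshots: Sequence[nx.Graph] | Mapping[Hashable, nx.Graph],
        times: Iterable[Hashable] | None = None,
    ) -> "DynamicNetwork":
        """Build a network from a sequence or mapping of snapshot graphs."""
        if isinstance(snapshots, Mapping):
            tlist = list(snapshots) if times is None else list(times)
            smap = dict(snapshots)
        else:
            tlist = list(range(1, len(snapshots) + 1)) if times is None else list(times)
            if len(tlist) != len(snapshots):
                raise DynamicNetworkError("times and snapshots differ in length")
            smap = dict(zip(tlist, snapshots))
        return cls(times=tlist, snapshots=smap)
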