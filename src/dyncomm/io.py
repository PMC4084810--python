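"""Reading dynamic networks and writing community reports.

Two input dialects are supported:

* **dynamic GEXF** (1.2/1.3): nodes and edges carry lifetimes as spells
  (``<spells><spell start=... end=.../></spells>``), as ``start``/``end``
  attributes, or as a single ``timestamp``.  The analysed snapshots are
  taken at the sorted distinct *start* values (and timestamps) found in the
  file, and an interval ``[start, end)`` is treated as closed on the start
  and open on the end, so an element whose spell is ``[1, 2)`` belongs to
  the snapshot at 1 but not at 2.  An edge is included in a snapshot only
  while both its endpoints are alive.
* **edge lists**: one whitespace-separated file per snapshot, lines
  ``u v [weight]`` (weight defaults to 1); a line with a single token
  declares an isolated present node; ``#`` starts a comment.  The order of
  the files defines the time order.

The writers emit a CSV membership table (RFC 4180, UTF-8, header row,
stable column order) and an HTML report with nodes as columns and time
steps as rows, every community rendered with a deterministic colour.  Both
carry the same membership content.
"""

from __future__ import annotations

import csv
import html
import math
import zlib
from pathlib import Path
from typing import Hashable, Sequence

import networkx as nx
from lxml import etree

from .cost import HomeAssignment, community_present
from .network import ABSENT, DynamicNetwork, DynamicNetworkError
from .subcommunity import UNASSIGNED, SubCommunityAssignment


class GexfError(ValueError):
    """Raised for malformed or unusable GEXF input."""


# ---------------------------------------------------------------------------
# readers


def _num(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise GexfError(
            f"non-numeric {what} {text!r}; only numeric time keys are supported "
            "(timeformat 'date' is not)"
        ) from exc


def _lifetimes(el) -> list[tuple[float, float]]:
    """Collect [start, end) intervals for one node/edge element."""
    spells = []
    for spell in el.iter("{*}spell"):
        s = spell.get("start")
        e = spell.get("end")
        spells.append(
            (
                -math.inf if s is None else _num(s, "spell start"),
                math.inf if e is None else _num(e, "spell end"),
            )
        )
    if spells:
        return spells
    ts = el.get("timestamp")
    if ts is not None:
        v = _num(ts, "timestamp")
        return [(v, v)]  # degenerate: present exactly at v
    s, e = el.get("start"), el.get("end")
    if s is not None or e is not None:
        return [
            (
                -math.inf if s is None else _num(s, "start"),
                math.inf if e is None else _num(e, "end"),
            )
        ]
    return []  # element carries no timing information


def _alive(spells: list[tuple[float, float]], t: float) -> bool:
    # closed-open [start, end); a degenerate [v, v] covers exactly v
    return any(s <= t < e or t == s for s, e in spells)


def read_dynamic_gexf(path) -> DynamicNetwork:
    """Read a dynamic GEXF file into a :class:`DynamicNetwork`.

    Observation times are the sorted distinct start values (and
    timestamps) over all node and edge lifetimes.  Elements with no timing
    information at all are treated as always alive, but a file where *no*
    element carries timing is rejected as static.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GexfError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    graphs = [el for el in root.iter() if etree.QName(el).localname == "graph"]
    if not graphs:
        raise GexfError(f"{path}: no <graph> element found")
    graph_el = graphs[0]

    node_spells: dict[str, list] = {}
    edges: list[tuple[str, str, float, list]] = []
    any_dynamic = False
    for el in graph_el.iter():
        name = etree.QName(el).localname
        if name == "node":
            nid = el.get("id")
            if nid is None:
                raise GexfError(f"{path}: node without id (line {el.sourceline})")
            spells = _lifetimes(el)
            any_dynamic = any_dynamic or bool(spells)
            node_spells[nid] = spells
        elif name == "edge":
            u, v = el.get("source"), el.get("target")
            if u is None or v is None:
                raise GexfError(f"{path}: edge without endpoints (line {el.sourceline})")
            if u == v:
                raise GexfError(f"{path}: self-loop on node {u!r} (line {el.sourceline})")
            w = float(el.get("weight", "1"))
            if not (math.isfinite(w) and w > 0):
                raise GexfError(f"{path}: invalid edge weight {w!r} (line {el.sourceline})")
            spells = _lifetimes(el)
            any_dynamic = any_dynamic or bool(spells)
            edges.append((u, v, w, spells))

    if not any_dynamic:
        raise GexfError(
            f"{path}: GEXF carries no dynamics (no spells, timestamps or "
            "start/end attributes); for static snapshots use the edge-list "
            "reader with one file per snapshot"
        )

    starts: set[float] = set()
    for spells in node_spells.values():
        starts.update(s for s, _e in spells if math.isfinite(s))
    for _u, _v, _w, spells in edges:
        starts.update(s for s, _e in spells if math.isfinite(s))
    times = sorted(starts)
    if len(times) < 2:
        raise GexfError(
            f"{path}: only {len(times)} distinct observation time(s) found; "
            "a dynamic network needs at least 2"
        )

    def nice(t: float):
        return int(t) if float(t).is_integer() else t

    snapshots: dict[Hashable, nx.Graph] = {}
    tkeys = [nice(t) for t in times]
    for t, tk in zip(times, tkeys):
        g = nx.Graph(time=tk)
        for nid, spells in node_spells.items():
            if not spells or _alive(spells, t):
                g.add_node(nid)
        for u, v, w, spells in edges:
            if (not spells or _alive(spells, t)) and g.has_node(u) and g.has_node(v):
                g.add_edge(u, v, weight=w)
        snapshots[tk] = g
    return DynamicNetwork(times=tkeys, snapshots=snapshots, node_ids=list(node_spells))


def read_edge_lists(paths: Sequence) -> DynamicNetwork:
    """Read one whitespace edge-list file per snapshot, in time order."""
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise DynamicNetworkError(
            f"got {len(paths)} snapshot file(s); a dynamic network needs at least 2"
        )
    snapshots: dict[Hashable, nx.Graph] = {}
    times = list(range(1, len(paths) + 1))
    for t, p in zip(times, paths):
        g = nx.Graph(time=t)
        with open(p, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                tok = line.split()
                if len(tok) == 1:
                    g.add_node(tok[0])
                    continue
                if len(tok) > 3:
                    raise DynamicNetworkError(
                        f"{p}:{lineno}: expected 'u v [weight]', got {len(tok)} fields"
                    )
                u, v = tok[0], tok[1]
                if u == v:
                    raise DynamicNetworkError(f"{p}:{lineno}: self-loop on node {u!r}")
                w = 1.0
                if len(tok) == 3:
                    try:
                        w = float(tok[2])
                    except ValueError:
                        raise DynamicNetworkError(
                            f"{p}:{lineno}: non-numeric edge weight {tok[2]!r}"
                        ) from None
                if not (math.isfinite(w) and w > 0):
                    raise DynamicNetworkError(
                        f"{p}:{lineno}: edge weight must be finite and > 0, got {w}"
                    )
                g.add_edge(u, v, weight=w)
        snapshots[t] = g
    return DynamicNetwork(times=times, snapshots=snapshots)


def write_edge_lists(network: DynamicNetwork, directory, prefix: str = "snapshot") -> list[Path]:
    """Serialise a network to the edge-list dialect, one file per snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, t in enumerate(network.times, start=1):
        g = network.snapshots[t]
        p = directory / f"{prefix}_{i:03d}.edges"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            for u, v, w in sorted(g.edges(data="weight", default=1.0)):
                fh.write(f"{u} {v} {w:g}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# writers


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:g}"
    return str(x)


def _membership_columns(timeline) -> list[str]:
    return [f"community_t{t}" for t in timeline.times]


def write_membership_csv(result: HomeAssignment | SubCommunityAssignment, path) -> None:
    """Write the per-node membership table as CSV.

    Column order (stable, documented): ``node``, one ``community_t<t>``
    column per time step (absence marker ``-`` where the node is absent),
    then model-specific columns — for the cost model ``home_t<t>`` per
    time, ``events_t<t>`` per time ('+'-joined event tags) and
    ``node_cost``; for the sub-community model ``subcommunity`` (``-``
    when unassigned), ``original_community`` and ``promiscuity``.
    """
    timeline = result.timeline
    header = ["node"] + _membership_columns(timeline)
    if isinstance(result, HomeAssignment):
        header += [f"home_t{t}" for t in timeline.times]
        header += [f"events_t{t}" for t in timeline.times]
        header += ["node_cost"]
    else:
        header += ["subcommunity", "original_community", "promiscuity"]

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for n in timeline.nodes:
            row = [str(n)] + [
                _fmt(timeline.membership[(n, t)]) for t in timeline.times
            ]
            if isinstance(result, HomeAssignment):
                row += [_fmt(result.home[(n, t)]) for t in timeline.times]
                row += ["+".join(result.itemised[(n, t)]) for t in timeline.times]
                row += [_fmt(result.node_cost[n])]
            else:
                lab = result.label[n]
                row += [
                    "-" if lab == UNASSIGNED else _fmt(lab),
                    _fmt(result.original[n]),
                    _fmt(result.promiscuity[n]),
                ]
            w.writerow(row)


_PALETTE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
    "#86bcb6", "#d37295", "#a0cbe8", "#ffbe7d", "#8cd17d",
    "#b6992d", "#499894", "#fabfd2", "#79706e", "#d4a6c8",
]


def community_colour(community) -> str:
    """Deterministic colour for a community or sub-community id."""
    return _PALETTE[zlib.crc32(str(community).encode()) % len(_PALETTE)]


def _box(label, colour: str | None, **data) -> str:
    attrs = "".join(f' data-{k}="{html.escape(str(v))}"' for k, v in data.items())
    style = f' style="background:{colour}"' if colour else ""
    return f"<span class=\"box\"{style}{attrs}>{html.escape(str(label))}</span>"


def write_html_report(
    result: HomeAssignment | SubCommunityAssignment,
    network: DynamicNetwork,
    path,
) -> None:
    """Write the HTML community-structure report.

    Nodes are columns and time steps rows; each community gets a
    deterministic colour and its number.  Cost-model cells show the home
    community on the left and, when it differs, the visited community on
    the right; absences are dashes, coloured with the home colour exactly
    when the home community is itself absent (no absence cost incurred).
    Sub-community reports add rows for the sub-community label, the
    original community and per-node member counts, with ``-`` for
    unassigned nodes.
    """
    timeline = result.timeline
    is_cost = isinstance(result, HomeAssignment)
    nodes = timeline.nodes
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\"><title>Dynamic community report</title>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;text-align:center}.box{display:inline-block;"
        "min-width:1.6em;padding:0 2px;margin:0 1px;border-radius:2px}</style>",
        "</head><body>",
        f"<h1>{'Cost model' if is_cost else 'Sub-community model'} report</h1>",
        "<table>",
        "<tr><th>time</th>"
        + "".join(f"<th>{html.escape(str(n))}</th>" for n in nodes)
        + "</tr>",
    ]

    if not is_cost:
        row = ["<tr><th>sub-community</th>"]
        for n in nodes:
            lab = result.label[n]
            if lab == UNASSIGNED:
                row.append(f"<td>{_box('-', None, node=n, subcommunity='-')}</td>")
            else:
                row.append(
                    f"<td>{_box(lab, community_colour(lab), node=n, subcommunity=lab)}</td>"
                )
        parts.append("".join(row) + "</tr>")
        row = ["<tr><th>original community</th>"]
        for n in nodes:
            c = result.original[n]
            row.append(f"<td>{_box(c, community_colour(c), node=n, original=c)}</td>")
        parts.append("".join(row) + "</tr>")

    for t in timeline.times:
        row = [f"<tr><th>{html.escape(str(t))}</th>"]
        for n in nodes:
            m = timeline.membership[(n, t)]
            cell = []
            if is_cost:
                h = result.home[(n, t)]
                if m == ABSENT:
                    home_absent = not community_present(timeline, h, t)
                    cell.append(_box(h, community_colour(h), node=n, time=t, home=h))
                    cell.append(
                        _box(
                            "-",
                            community_colour(h) if home_absent else None,
                            node=n, time=t, community="-",
                        )
                    )
                elif m == h:
                    cell.append(
                        _box(h, community_colour(h), node=n, time=t, home=h, community=m)
                    )
                else:  # visiting a community of which the node is not a member
                    cell.append(_box(h, community_colour(h), node=n, time=t, home=h))
                    cell.append(_box(m, community_colour(m), node=n, time=t, community=m))
            else:
                if m == ABSENT:
                    cell.append(_box("-", None, node=n, time=t, community="-"))
                else:
                    cell.append(_box(m, community_colour(m), node=n, time=t, community=m))
            row.append(f"<td>{''.join(cell)}</td>")
        parts.append("".join(row) + "</tr>")

    if not is_cost:
        row = ["<tr><th>members</th>"]
        for n in nodes:
            lab = result.label[n]
            count = "-" if lab == UNASSIGNED else result.sizes[lab]
            row.append(f"<td data-members=\"{count}\">{count}</td>")
        parts.append("".join(row) + "</tr>")
    else:
        row = ["<tr><th>node cost</th>"]
        for n in nodes:
            row.append(f"<td>{_fmt(result.node_cost[n])}</td>")
        parts.append("".join(row) + "</tr>")

    parts += ["</table>", "</body></html>"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(parts) + "\n")
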