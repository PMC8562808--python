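"""Vegetation-map data model: graph construction, edge directionality,
line-graph conversion, observed-network extraction, and map I/O.

A vegetation map is a connected graph of junction nodes and stem edges with
physical lengths (cm).  Every ordered pair of adjacent edges carries a
transition index (TI) in {1, 2, 3, 4} estimating how likely successive ants
are to take the same trajectory through the shared junction (1 = one forced
trajectory on a single plant, 4 = many wind-perturbed trajectories).  Each
observation day records the terminals (nests and food sources), the edges
observed in use, and edges ruptured from that day onward.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

TI_VALUES = frozenset({1, 2, 3, 4})


class MapError(ValueError):
    """Raised when a vegetation map violates a structural invariant."""


@dataclass(frozen=True)
class DayRecord:
    """One observation day: terminal set, used edges, and ruptures.

    ``removed_edges`` take effect cumulatively from this day forward.
    """

    day_index: int
    terminals: frozenset[str]
    used_edges: frozenset[str] = frozenset()
    removed_edges: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise MapError(f"day_index must be >= 1, got {self.day_index}")
        overlap = self.used_edges & self.removed_edges
        if overlap:
            raise MapError(
                f"day {self.day_index}: edges {sorted(overlap)} both used and removed"
            )


@dataclass(frozen=True)
class Edge:
    edge_id: str
    u: str
    v: str
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise MapError(f"edge {self.edge_id}: length must be > 0, got {self.length}")

    @property
    def endpoints(self) -> frozenset[str]:
        return frozenset((self.u, self.v))

    def other(self, node: str) -> str:
        if node == self.u:
            return self.v
        if node == self.v:
            return self.u
        raise KeyError(f"{node} is not an endpoint of edge {self.edge_id}")


@dataclass
class VegetationMap:
    """The graph of available vegetation with lengths, TIs and days.

    ``transitions`` is keyed by the ordered triple
    ``(incoming edge-id, via node-id, outgoing edge-id)``.
    ``root_terminal`` anchors the outbound direction: the outbound direction
    of every edge points away from this terminal.
    """

    nodes: dict[str, Optional[str]]  # node-id -> plant label (or None)
    edges: dict[str, Edge]
    transitions: dict[tuple[str, str, str], int]
    days: list[DayRecord]
    root_terminal: str
    colony: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    # -- derived caches (not serialized) --
    _orientation: Optional[dict[str, tuple[str, str]]] = field(
        default=None, repr=False, compare=False
    )

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def validate(self) -> None:
        for eid, e in self.edges.items():
            if e.u not in self.nodes or e.v not in self.nodes:
                raise MapError(f"edge {eid} references unknown node")
        for (ein, v, eout), ti in self.transitions.items():
            if ti not in TI_VALUES:
                raise MapError(f"transition ({ein},{v},{eout}): ti={ti} not in 1..4")
            for eid in (ein, eout):
                if eid not in self.edges:
                    raise MapError(f"transition references unknown edge {eid}")
            if v not in self.edges[ein].endpoints or v not in self.edges[eout].endpoints:
                raise MapError(f"transition ({ein},{v},{eout}): {v} not shared endpoint")
        if self.root_terminal not in self.nodes:
            raise MapError(f"root terminal {self.root_terminal!r} not a node")
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for e in self.edges.values():
            deg[e.u] += 1
            deg[e.v] += 1
        low = [n for n, d in deg.items() if d < 3]
        if low:
            raise MapError(f"nodes with fewer than 3 incident edges: {sorted(low)[:10]}")
        for day in self.days:
            bad = day.terminals - self.nodes.keys()
            if bad:
                raise MapError(f"day {day.day_index}: unknown terminals {sorted(bad)}")
            g = self.graph(day.day_index)
            if g.number_of_nodes() and not nx.is_connected(g):
                raise MapError(f"day {day.day_index}: available subgraph disconnected")
            used = self.graph(day.day_index, edge_ids=day.used_edges)
            terms = [t for t in day.terminals if t in used]
            if day.used_edges and (
                set(day.terminals) - set(used.nodes)
                or (terms and not _all_connected(used, terms))
            ):
                warnings.warn(
                    f"day {day.day_index}: used edges do not connect all terminals",
                    stacklevel=2,
                )

    def day(self, day_index: int) -> DayRecord:
        for d in self.days:
            if d.day_index == day_index:
                return d
        raise KeyError(f"no day {day_index} in map")

    def removed_through(self, day_index: int) -> frozenset[str]:
        """Edges unavailable on ``day_index`` (ruptures are cumulative)."""
        out: set[str] = set()
        for d in self.days:
            if d.day_index <= day_index:
                out |= d.removed_edges
        return frozenset(out)

    def available_edges(self, day_index: Optional[int] = None) -> frozenset[str]:
        if day_index is None:
            return frozenset(self.edges)
        return frozenset(self.edges) - self.removed_through(day_index)

    def graph(
        self,
        day_index: Optional[int] = None,
        edge_ids: Optional[Iterable[str]] = None,
    ) -> nx.Graph:
        """Undirected view of (a subset of) the map's edges.

        With only ``day_index``, the day's available subgraph; with
        ``edge_ids``, exactly those edges.  Nodes are induced from edges.
        """
        if edge_ids is None:
            edge_ids = self.available_edges(day_index)
        g = nx.Graph()
        for eid in edge_ids:
            e = self.edges[eid]
            g.add_edge(e.u, e.v, edge_id=eid, length=e.length)
        return g

    def edge_between(self, u: str, v: str) -> Edge:
        eid = self._pair_index().get(frozenset((u, v)))
        if eid is None:
            raise KeyError(f"no edge between {u} and {v}")
        return self.edges[eid]

    def _pair_index(self) -> dict[frozenset[str], str]:
        idx = self.metadata.get("_pair_index")
        if idx is None:
            idx = {e.endpoints: eid for eid, e in self.edges.items()}
            self.metadata["_pair_index"] = idx
        return idx

    def invalidate_caches(self) -> None:
        self.metadata.pop("_pair_index", None)
        self._orientation = None

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "colony": self.colony,
            "root_terminal": self.root_terminal,
            "nodes": [
                {"id": n, "plant": p} for n, p in sorted(self.nodes.items())
            ],
            "edges": [
                {"id": e.edge_id, "u": e.u, "v": e.v, "length_cm": e.length}
                for e in sorted(self.edges.values(), key=lambda e: e.edge_id)
            ],
            "transitions": [
                {"edge_in": k[0], "node": k[1], "edge_out": k[2], "ti": ti}
                for k, ti in sorted(self.transitions.items())
            ],
            "days": [
                {
                    "day": d.day_index,
                    "terminals": sorted(d.terminals),
                    "used_edges": sorted(d.used_edges),
                    "removed_edges": sorted(d.removed_edges),
                }
                for d in self.days
            ],
            "metadata": {
                k: v for k, v in self.metadata.items() if not k.startswith("_")
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "VegetationMap":
        doc = json.loads(text)
        m = cls(
            nodes={n["id"]: n.get("plant") for n in doc["nodes"]},
            edges={
                e["id"]: Edge(e["id"], e["u"], e["v"], float(e["length_cm"]))
                for e in doc["edges"]
            },
            transitions={
                (t["edge_in"], t["node"], t["edge_out"]): int(t["ti"])
                for t in doc["transitions"]
            },
            days=[
                DayRecord(
                    day_index=int(d["day"]),
                    terminals=frozenset(d["terminals"]),
                    used_edges=frozenset(d.get("used_edges", ())),
                    removed_edges=frozenset(d.get("removed_edges", ())),
                )
                for d in doc["days"]
            ],
            root_terminal=doc["root_terminal"],
            colony=doc.get("colony", "unknown"),
            metadata=doc.get("metadata", {}),
        )
        return m

    def to_csv(self) -> dict[str, str]:
        """CSV alternative: edges.csv, transitions.csv, days.csv, nodes.csv."""
        out: dict[str, str] = {}

        def _table(header: Sequence[str], rows: Iterable[Sequence]) -> str:
            buf = io.StringIO()
            w = csv.writer(buf, lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)
            return buf.getvalue()

        out["nodes.csv"] = _table(
            ["node_id", "plant"],
            [(n, p or "") for n, p in sorted(self.nodes.items())],
        )
        out["edges.csv"] = _table(
            ["edge_id", "u", "v", "length_cm"],
            [
                (e.edge_id, e.u, e.v, repr(e.length))
                for e in sorted(self.edges.values(), key=lambda e: e.edge_id)
            ],
        )
        out["transitions.csv"] = _table(
            ["edge_in", "node", "edge_out", "ti"],
            [(k[0], k[1], k[2], ti) for k, ti in sorted(self.transitions.items())],
        )
        out["days.csv"] = _table(
            ["day", "terminals", "used_edges", "removed_edges"],
            [
                (
                    d.day_index,
                    ";".join(sorted(d.terminals)),
                    ";".join(sorted(d.used_edges)),
                    ";".join(sorted(d.removed_edges)),
                )
                for d in self.days
            ],
        )
        return out

    @classmethod
    def from_csv(
        cls,
        edges_csv: str,
        transitions_csv: str,
        days_csv: str,
        root_terminal: str,
        nodes_csv: Optional[str] = None,
        colony: str = "unknown",
    ) -> "VegetationMap":
        edges = {
            r["edge_id"]: Edge(r["edge_id"], r["u"], r["v"], float(r["length_cm"]))
            for r in csv.DictReader(io.StringIO(edges_csv))
        }
        nodes: dict[str, Optional[str]] = {}
        if nodes_csv:
            for r in csv.DictReader(io.StringIO(nodes_csv)):
                nodes[r["node_id"]] = r["plant"] or None
        for e in edges.values():
            nodes.setdefault(e.u, None)
            nodes.setdefault(e.v, None)
        transitions = {
            (r["edge_in"], r["node"], r["edge_out"]): int(r["ti"])
            for r in csv.DictReader(io.StringIO(transitions_csv))
        }

        def _split(s: str) -> frozenset[str]:
            return frozenset(x for x in s.split(";") if x)

        days = [
            DayRecord(
                int(r["day"]),
                _split(r["terminals"]),
                _split(r["used_edges"]),
                _split(r["removed_edges"]),
            )
            for r in csv.DictReader(io.StringIO(days_csv))
        ]
        return cls(nodes, edges, transitions, days, root_terminal, colony)

    def to_graphml(self, day_index: Optional[int] = None) -> str:
        """GraphML export of one day's available graph (or the full map)."""
        g = self.graph(day_index)
        for n in g.nodes:
            g.nodes[n]["plant"] = self.nodes.get(n) or ""
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()


def _all_connected(g: nx.Graph, nodes: Sequence[str]) -> bool:
    if not nodes:
        return True
    if any(n not in g for n in nodes):
        return False
    seen = set(nx.node_connected_component(g, nodes[0]))
    return all(n in seen for n in nodes)


# ----------------------------------------------------------------------
# directionality
# ----------------------------------------------------------------------
def orient_outbound(vmap: VegetationMap) -> dict[str, tuple[str, str]]:
    """Assign every edge its single outbound direction, away from the root.

    The orientation is a breadth-first ordering from ``root_terminal`` on the
    full map: each edge is directed from the endpoint nearer the root (in hop
    count) to the farther one; edges between equidistant endpoints are
    directed toward the lexicographically larger node-id.  The result maps
    edge-id to ``(tail, head)`` with the head on the outbound side, and is
    cached on the map (idempotent).
    """
    if vmap._orientation is not None:
        return vmap._orientation
    g = vmap.graph(None)
    root = vmap.root_terminal
    if root not in g:
        raise MapError(f"root terminal {root!r} is isolated")
    hops = nx.single_source_shortest_path_length(g, root)
    orphans = sorted(set(g.nodes) - set(hops))
    if orphans:
        raise MapError(f"nodes with no path to root {root!r}: {orphans}")
    orient: dict[str, tuple[str, str]] = {}
    for eid, e in vmap.edges.items():
        hu, hv = hops[e.u], hops[e.v]
        if hu < hv or (hu == hv and e.u < e.v):
            orient[eid] = (e.u, e.v)
        else:
            orient[eid] = (e.v, e.u)
    vmap._orientation = orient
    return orient


def outbound_digraph(
    vmap: VegetationMap,
    day_index: Optional[int] = None,
    edge_ids: Optional[Iterable[str]] = None,
) -> nx.DiGraph:
    """Directed (outbound) view of a day's available edges or a given subset."""
    orient = orient_outbound(vmap)
    if edge_ids is None:
        edge_ids = vmap.available_edges(day_index)
    g = nx.DiGraph()
    for eid in edge_ids:
        tail, head = orient[eid]
        g.add_edge(tail, head, edge_id=eid, length=vmap.edges[eid].length)
    return g


# ----------------------------------------------------------------------
# line graph
# ----------------------------------------------------------------------
@dataclass
class LineGraph:
    """Line graph of the vegetation map: nodes are map edges, edges are
    outbound transitions weighted by their transition index."""

    graph: nx.DiGraph  # line-node = edge-id; line-edge (e_in -> e_out), weight=ti
    day_index: Optional[int] = None

    @property
    def n_line_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_line_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)


def to_line_graph(vmap: VegetationMap, day_index: Optional[int] = None) -> LineGraph:
    """Build the line graph of a day's available subgraph.

    One line-node per available map edge; one line-edge per outbound
    transition (incoming edge, junction, outgoing edge) whose three elements
    are all available, weighted by the transition index.
    """
    avail = vmap.available_edges(day_index)
    if not avail:
        raise MapError(f"day {day_index}: no available edges")
    orient = orient_outbound(vmap)
    lg = nx.DiGraph()
    lg.add_nodes_from(sorted(avail))
    for ein, v, eout, ti in transitions_of(avail, vmap):
        lg.add_edge(ein, eout, node=v, ti=ti, weight=ti)
    return LineGraph(lg, day_index)


def adjacent_pairs_line_graph(
    vmap: VegetationMap, day_index: Optional[int] = None
) -> nx.Graph:
    """Undirected line graph over all adjacent edge pairs.

    Unlike :func:`to_line_graph`, which keeps only outbound transitions
    (and is therefore cut at junctions whose edges all point outbound,
    e.g. the root), this view joins every pair of available edges sharing a
    junction, weighted by the TI of the pair (the smaller of the two
    ordered records if they differ).  It is connected whenever the map is,
    which the optimizers rely on.
    """
    avail = vmap.available_edges(day_index)
    incident: dict[str, list[str]] = {}
    for eid in sorted(avail):
        e = vmap.edges[eid]
        incident.setdefault(e.u, []).append(eid)
        incident.setdefault(e.v, []).append(eid)
    lg = nx.Graph()
    lg.add_nodes_from(sorted(avail))
    for v, inc in sorted(incident.items()):
        for i in range(len(inc)):
            for j in range(i + 1, len(inc)):
                e1, e2 = inc[i], inc[j]
                tis = [
                    t
                    for t in (
                        vmap.transitions.get((e1, v, e2)),
                        vmap.transitions.get((e2, v, e1)),
                    )
                    if t is not None
                ]
                if not tis:
                    raise MapError(
                        f"no transition record for adjacent pair ({e1}, {v}, {e2})"
                    )
                ti = min(tis)
                if not lg.has_edge(e1, e2) or lg.edges[e1, e2]["ti"] > ti:
                    lg.add_edge(e1, e2, node=v, ti=ti, weight=ti)
    return lg


def transitions_of(
    edge_ids: Iterable[str], vmap: VegetationMap
) -> list[tuple[str, str, str, int]]:
    """All outbound transitions among a set of edges.

    Every ordered adjacent pair (e_in into v, e_out away from v, in the
    outbound orientation) with both edges in ``edge_ids`` yields one
    transition ``(e_in, v, e_out, ti)``.  A missing transition record is an
    error naming the pair.
    """
    orient = orient_outbound(vmap)
    ids = set(edge_ids)
    into: dict[str, list[str]] = {}
    outof: dict[str, list[str]] = {}
    for eid in ids:
        tail, head = orient[eid]
        into.setdefault(head, []).append(eid)
        outof.setdefault(tail, []).append(eid)
    out: list[tuple[str, str, str, int]] = []
    for v in sorted(set(into) & set(outof)):
        for ein in sorted(into[v]):
            for eout in sorted(outof[v]):
                if ein == eout:
                    continue
                ti = vmap.transitions.get((ein, v, eout))
                if ti is None:
                    raise MapError(
                        f"no transition record for adjacent pair ({ein}, {v}, {eout})"
                    )
                out.append((ein, v, eout, ti))
    return out


# ----------------------------------------------------------------------
# trail networks
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TrailNetwork:
    """A trail network: an edge subset of the map on one day.

    ``provenance`` is one of ``observed``, ``random-dependent``,
    ``random-independent`` or ``optimized-<objective>``.  Random networks
    additionally carry the per-terminal connecting walks and the endpoint
    set (nodes at which walks attached).
    """

    day_index: int
    edge_ids: frozenset[str]
    node_ids: frozenset[str]
    provenance: str
    terminal_walks: Optional[Mapping[str, tuple[str, ...]]] = None
    endpoints: Optional[frozenset[str]] = None

    def graph(self, vmap: VegetationMap) -> nx.Graph:
        g = vmap.graph(edge_ids=self.edge_ids)
        g.add_nodes_from(self.node_ids)
        return g

    def digraph(self, vmap: VegetationMap) -> nx.DiGraph:
        g = outbound_digraph(vmap, edge_ids=self.edge_ids)
        g.add_nodes_from(self.node_ids)
        return g


def network_from_edges(
    vmap: VegetationMap,
    day_index: int,
    edge_ids: Iterable[str],
    provenance: str,
    extra_nodes: Iterable[str] = (),
    **kw,
) -> TrailNetwork:
    edge_ids = frozenset(edge_ids)
    nodes: set[str] = set(extra_nodes)
    for eid in edge_ids:
        e = vmap.edges[eid]
        nodes.add(e.u)
        nodes.add(e.v)
    return TrailNetwork(day_index, edge_ids, frozenset(nodes), provenance, **kw)


def observed_network(vmap: VegetationMap, day_index: int) -> TrailNetwork:
    """The trail network the ants were observed to use on one day."""
    day = vmap.day(day_index)
    if not day.used_edges:
        raise MapError(f"day {day_index}: no observed network (empty used set)")
    gone = day.used_edges & vmap.removed_through(day_index)
    if gone:
        raise MapError(
            f"day {day_index}: used edges {sorted(gone)} are listed as removed"
        )
    return network_from_edges(
        vmap, day_index, day.used_edges, "observed", extra_nodes=day.terminals
    )
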