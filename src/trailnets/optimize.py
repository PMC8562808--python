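"""Heuristic trail networks optimizing each objective independently.

Four objectives, four heuristics:

* average edge length — greedy add-then-prune on edge lengths;
* average transition index — the same greedy scheme run on the line graph,
  whose edge weights are the transition indices (the exact problem is
  NP-complete, see :mod:`trailnets.oracles`);
* total nodes — metric-closure Steiner-tree approximation with unit (hop)
  edge weights;
* total edge length — a level-2 density-greedy directed Steiner heuristic
  rooted at a designated nest.

All heuristics return a connected network containing all of the day's
terminals; none guarantees global optimality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
from networkx.algorithms.approximation import steiner_tree

from trailnets.core import (
    MapError,
    TrailNetwork,
    VegetationMap,
    network_from_edges,
    orient_outbound,
    outbound_digraph,
    transitions_of,
)

logger = logging.getLogger(__name__)

OBJECTIVES = ("avg_edge_length", "total_nodes", "avg_ti", "total_length")


@dataclass(frozen=True)
class OptimizedNetwork:
    network: TrailNetwork
    objective: str
    achieved: Optional[float]


class UnreachableTerminalError(MapError):
    pass


def _check_reachable(g: nx.Graph, terminals: Iterable[str]) -> None:
    terminals = list(terminals)
    missing = [t for t in terminals if t not in g]
    if missing:
        raise UnreachableTerminalError(f"terminals not in available graph: {missing}")
    comp = nx.node_connected_component(g, terminals[0])
    out = [t for t in terminals if t not in comp]
    if out:
        raise UnreachableTerminalError(f"terminals unreachable: {out}")


def _terminals(vmap: VegetationMap, day_index: int, terminals=None) -> list[str]:
    if terminals is None:
        terminals = vmap.day(day_index).terminals
    return sorted(terminals)


# ----------------------------------------------------------------------
# average edge length
# ----------------------------------------------------------------------
def greedy_min_avg_length(
    vmap: VegetationMap, day_index: int, terminals=None
) -> OptimizedNetwork:
    """Greedy add-then-prune network minimizing the mean edge length.

    Edges are added in order of increasing length until all terminals lie in
    one connected component; everything outside that component is dropped;
    then edges are removed in decreasing length order whenever removal
    lowers the average length without disconnecting the network.
    """
    X = _terminals(vmap, day_index, terminals)
    g = vmap.graph(day_index)
    _check_reachable(g, X)
    if len(X) == 1:
        return OptimizedNetwork(
            TrailNetwork(day_index, frozenset(), frozenset(X), "optimized-avg_edge_length"),
            "avg_edge_length",
            None,
        )
    order = sorted(vmap.available_edges(day_index), key=lambda eid: (vmap.edges[eid].length, eid))
    t = nx.Graph()
    for eid in order:
        e = vmap.edges[eid]
        t.add_edge(e.u, e.v, edge_id=eid, length=e.length)
        if all(x in t for x in X) and _same_component(t, X):
            break
    comp = set(nx.node_connected_component(t, X[0]))
    t.remove_nodes_from([n for n in list(t.nodes) if n not in comp])
    _prune_by_average(t, X, score=lambda d: d["length"])
    edges = [d["edge_id"] for _, _, d in t.edges(data=True)]
    lengths = [vmap.edges[eid].length for eid in edges]
    return OptimizedNetwork(
        network_from_edges(vmap, day_index, edges, "optimized-avg_edge_length", extra_nodes=X),
        "avg_edge_length",
        sum(lengths) / len(lengths) if lengths else None,
    )


def _same_component(g: nx.Graph, nodes: list[str]) -> bool:
    comp = nx.node_connected_component(g, nodes[0])
    return all(n in comp for n in nodes)


def _prune_by_average(t: nx.Graph, terminals: list[str], score) -> None:
    """Remove edges in decreasing score order while removal lowers the mean
    score and keeps the (terminal-containing) network connected."""
    changed = True
    while changed:
        changed = False
        edges = sorted(
            t.edges(data=True), key=lambda uvd: (-score(uvd[2]), uvd[2].get("edge_id", ""))
        )
        total = sum(score(d) for _, _, d in edges)
        k = len(edges)
        for u, v, d in edges:
            if k <= 1:
                break
            s = score(d)
            # removing s lowers the mean iff s exceeds the mean of the rest
            if s <= (total - s) / (k - 1):
                continue
            t.remove_edge(u, v)
            isolated = [n for n in (u, v) if t.degree(n) == 0 and n not in terminals]
            t.remove_nodes_from(isolated)
            if t.number_of_nodes() and nx.is_connected(t) and all(x in t for x in terminals):
                total -= s
                k -= 1
                changed = True
            else:  # undo
                t.add_edge(u, v, **d)


# ----------------------------------------------------------------------
# average transition index
# ----------------------------------------------------------------------
def greedy_min_avg_ti(
    vmap: VegetationMap, day_index: int, terminals=None
) -> OptimizedNetwork:
    """Add-then-remove heuristic minimizing the realized average TI.

    The add phase admits edges in increasing transition-index order until
    the terminals' component closes (on the all-adjacent-pairs line graph
    this closure is the terminals' connected component of the day's
    available graph).  The removal phase then runs steepest descent on the
    network's realized average TI — the mean over every activated outbound
    transition, which is how networks are scored — removing at each step
    the edge whose removal lowers the average most, provided every
    terminal stays covered and the network stays connected.  Removals that
    leave the average unchanged are also taken (TI is a small integer
    scale; without tie removal every redundant branch of the lowest class
    would survive).
    """
    X = _terminals(vmap, day_index, terminals)
    g = vmap.graph(day_index)
    _check_reachable(g, X)
    if len(X) == 1:
        return OptimizedNetwork(
            TrailNetwork(day_index, frozenset(), frozenset(X), "optimized-avg_ti"),
            "avg_ti",
            None,
        )
    # single map edge covering all terminals (2 terminals joined directly)
    for eid in sorted(vmap.available_edges(day_index)):
        if set(X) <= vmap.edges[eid].endpoints:
            return OptimizedNetwork(
                network_from_edges(vmap, day_index, [eid], "optimized-avg_ti", extra_nodes=X),
                "avg_ti",
                None,
            )
    comp = nx.node_connected_component(g, X[0])
    net_edges = {
        d["edge_id"] for _, _, d in g.subgraph(comp).edges(data=True)
    }
    achieved = _remove_phase_ti(net_edges, X, vmap)
    return OptimizedNetwork(
        network_from_edges(
            vmap, day_index, sorted(net_edges), "optimized-avg_ti", extra_nodes=X
        ),
        "avg_ti",
        achieved,
    )


def _remove_phase_ti(
    net_edges: set[str], X: list[str], vmap: VegetationMap
) -> Optional[float]:
    """Steepest-descent removal on the realized average TI.

    Maintains the activated-transition sum and count incrementally; each
    step evaluates the removal delta of every edge from the incident
    structure, tries candidates in order of resulting average, and accepts
    the first one that preserves terminal coverage and connectivity.
    """
    orient = orient_outbound(vmap)
    trans = transitions_of(net_edges, vmap)
    S = float(sum(t[3] for t in trans))
    C = len(trans)
    if C == 0:
        return None

    def delta(eid: str) -> tuple[float, int]:
        """TI sum and count of transitions that vanish if eid is removed."""
        tail, head = orient[eid]
        ds, dc = 0.0, 0
        for v, as_in in ((head, True), (tail, False)):
            for other in net_edges:
                if other == eid:
                    continue
                ot, oh = orient[other]
                if as_in and ot == v:  # eid -> v -> other
                    ds += vmap.transitions[(eid, v, other)]
                    dc += 1
                elif not as_in and oh == v:  # other -> v -> eid
                    ds += vmap.transitions[(other, v, eid)]
                    dc += 1
        return ds, dc

    # incident index for fast delta evaluation
    while len(net_edges) > 1 and C > 0:
        by_node: dict[str, list[str]] = {}
        for e in net_edges:
            t, h = orient[e]
            by_node.setdefault(t, []).append(e)
            by_node.setdefault(h, []).append(e)
        cands = []
        cur = S / C
        for eid in sorted(net_edges):
            tail, head = orient[eid]
            ds, dc = 0.0, 0
            for other in by_node.get(head, ()):
                if other != eid and orient[other][0] == head:
                    ds += vmap.transitions[(eid, head, other)]
                    dc += 1
            for other in by_node.get(tail, ()):
                if other != eid and orient[other][1] == tail:
                    ds += vmap.transitions[(other, tail, eid)]
                    dc += 1
            if C - dc <= 0:
                continue
            new_avg = (S - ds) / (C - dc)
            if new_avg <= cur + 1e-12:
                cands.append((new_avg, eid, ds, dc))
        cands.sort()
        accepted = False
        for new_avg, eid, ds, dc in cands:
            candidate = net_edges - {eid}
            cov: set[str] = set()
            for e in candidate:
                cov |= vmap.edges[e].endpoints
            if not set(X) <= cov:
                continue
            if not nx.is_connected(vmap.graph(edge_ids=candidate)):
                continue
            net_edges.discard(eid)
            S -= ds
            C -= dc
            accepted = True
            break
        if not accepted:
            break
    return S / C if C else None


# ----------------------------------------------------------------------
# total nodes
# ----------------------------------------------------------------------
def approx_min_total_nodes(
    vmap: VegetationMap, day_index: int, terminals=None
) -> OptimizedNetwork:
    """Steiner-tree approximation minimizing the number of nodes.

    Runs the classic metric-closure (Kou-Markowsky-Berman) 2-approximation
    with unit hop weights, then prunes non-terminal leaves.  Node count is
    within twice the optimum.
    """
    X = _terminals(vmap, day_index, terminals)
    g = vmap.graph(day_index)
    _check_reachable(g, X)
    if len(X) == 1:
        return OptimizedNetwork(
            TrailNetwork(day_index, frozenset(), frozenset(X), "optimized-total_nodes"),
            "total_nodes",
            1.0,
        )
    for _, _, d in g.edges(data=True):
        d["hop"] = 1
    t = steiner_tree(g, X, weight="hop", method="kou").copy()
    _prune_leaves(t, X)
    edges = [d["edge_id"] for _, _, d in t.edges(data=True)]
    net = network_from_edges(vmap, day_index, edges, "optimized-total_nodes", extra_nodes=X)
    return OptimizedNetwork(net, "total_nodes", float(len(net.node_ids)))


def _prune_leaves(t: nx.Graph, terminals: list[str]) -> None:
    keep = set(terminals)
    while True:
        leaves = [n for n in t.nodes if t.degree(n) <= 1 and n not in keep]
        if not leaves:
            return
        t.remove_nodes_from(leaves)


# ----------------------------------------------------------------------
# total length
# ----------------------------------------------------------------------
def approx_min_total_length(
    vmap: VegetationMap,
    day_index: int,
    terminals=None,
    root: Optional[str] = None,
) -> OptimizedNetwork:
    """Directed Steiner heuristic minimizing the total edge length.

    A level-2 density-greedy scheme in the outbound view: repeatedly choose
    the intermediate vertex v and terminal subset minimizing
    (length of root->v plus the cheapest v->terminal paths) per terminal
    covered; bought edges become free for later iterations.  Falls back to
    the undirected graph, with a warning, if a terminal is unreachable in
    the outbound orientation.
    """
    X = _terminals(vmap, day_index, terminals)
    gu = vmap.graph(day_index)
    _check_reachable(gu, X)
    if root is None:
        root = vmap.root_terminal if vmap.root_terminal in X else X[0]
    if len(X) == 1:
        return OptimizedNetwork(
            TrailNetwork(day_index, frozenset(), frozenset(X), "optimized-total_length"),
            "total_length",
            0.0,
        )
    g = outbound_digraph(vmap, day_index)
    reach = nx.descendants(g, root) | {root} if root in g else set()
    if not set(X) <= reach:
        warnings.warn(
            "terminals unreachable in outbound view; using undirected graph",
            stacklevel=2,
        )
        g = gu.to_directed()

    work = g.copy()  # lengths zeroed as edges are bought
    bought: set[str] = set()
    uncovered = set(X) - {root}
    guard = 0
    while uncovered:
        guard += 1
        if guard > len(X) + 5:
            raise RuntimeError("density-greedy failed to converge")
        d_root, p_root = nx.single_source_dijkstra(work, root, weight="length")
        # reverse distances terminal <- v
        rev = work.reverse(copy=False)
        d_term = {
            t: nx.single_source_dijkstra(rev, t, weight="length") for t in uncovered
        }
        best = None  # (density, v, [terminals])
        for v in work.nodes:
            if v not in d_root:
                continue
            reach_ts = sorted(
                ((d_term[t][0][v], t) for t in uncovered if v in d_term[t][0]),
            )
            if not reach_ts:
                continue
            cum = 0.0
            for j, (c, _) in enumerate(reach_ts, start=1):
                cum += c
                density = (d_root[v] + cum) / j
                key = (density, v, j)
                if best is None or key < best[:3]:
                    best = (density, v, j, [t for _, t in reach_ts[:j]])
        if best is None:
            raise UnreachableTerminalError(f"terminals unreachable: {sorted(uncovered)}")
        _, v, _, ts = best
        paths = [p_root[v]] + [list(reversed(d_term[t][1][v])) for t in ts]
        for path in paths:
            for a, b in zip(path, path[1:]):
                eid = work.edges[a, b]["edge_id"]
                if eid not in bought:
                    bought.add(eid)
                    work.edges[a, b]["length"] = 0.0
                    if work.has_edge(b, a):
                        work.edges[b, a]["length"] = 0.0
        uncovered -= set(ts)

    # prune redundant dangling branches
    t = vmap.graph(edge_ids=bought)
    _prune_leaves(t, X)
    edges = [d["edge_id"] for _, _, d in t.edges(data=True)]
    total = sum(vmap.edges[eid].length for eid in edges)
    net = network_from_edges(vmap, day_index, edges, "optimized-total_length", extra_nodes=X)
    return OptimizedNetwork(net, "total_length", total)


OPTIMIZER_FUNCS = {
    "avg_edge_length": greedy_min_avg_length,
    "avg_ti": greedy_min_avg_ti,
    "total_nodes": approx_min_total_nodes,
    "total_length": approx_min_total_length,
}


def optimize_all(vmap: VegetationMap, day_index: int, terminals=None) -> dict[str, OptimizedNetwork]:
    """Run all four heuristics for one day."""
    return {
        name: fn(vmap, day_index, terminals) for name, fn in OPTIMIZER_FUNCS.items()
    }
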