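"""Synthetic vegetation maps with planted observed trails.

The generator emulates the statistical structure of field-mapped canopy
vegetation: ~150-220 junction nodes, every node with at least 3 incident
stems, stem lengths spanning 100-fold (log-uniform from sub-centimeter to
over a meter), nodes clustered into plants so that same-plant transitions
carry TI 1 while cross-plant transitions draw higher indices, 5-11
observation days with terminal turnover, and occasional stem ruptures.

Planted "observed" trails are unions of minimum-transition-cost routes
from the root nest to each terminal (plus exploration-noise spurs and
occasional two-branch loops), so the planted networks display the field
pattern: few nodes and low TI relative to random networks, indifferent
average edge length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

from trailnets.core import (
    DayRecord,
    Edge,
    MapError,
    VegetationMap,
    network_from_edges,
    outbound_digraph,
)
from trailnets.stats import ObjectiveVector, compute_objectives

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenParams:
    """Generator parameters; defaults emulate the field maps.

    Lengths are in cm.  ``ti_probs_cross_plant`` are the probabilities of
    TI 2, 3, 4 for transitions that change plants (same-plant transitions
    always carry TI 1).
    """

    n_nodes: int = 200
    n_plants: int = 50
    degree_min: int = 3
    length_log10_range: tuple[float, float] = (0.5, 150.0)
    ti_probs_cross_plant: tuple[float, float, float] = (0.3, 0.4, 0.3)
    n_terminals_per_day: tuple[int, int] = (3, 6)
    terminal_cost_scale: float = 2.0  # softmin scale (in summed TI excess) for
    # terminal placement: colonies forage where coherent low-TI routes exist
    terminal_min_hops: int = 5
    n_days: int = 10
    terminal_turnover_prob: float = 0.2
    rupture_prob: float = 0.1
    exploration_noise: float = 0.05
    loop_insertion_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 20:
            raise ValueError("n_nodes must be >= 20")
        if abs(sum(self.ti_probs_cross_plant) - 1.0) > 1e-9:
            raise ValueError("ti_probs_cross_plant must sum to 1")
        for p in (
            self.terminal_turnover_prob,
            self.rupture_prob,
            self.exploration_noise,
            self.loop_insertion_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_nodes <= self.degree_min:
            raise MapError("degree constraint infeasible for n_nodes")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic colony, for recovery tests."""

    planted_edges: dict[int, frozenset[str]] = field(default_factory=dict)
    planted_objectives: dict[int, ObjectiveVector] = field(default_factory=dict)
    rupture_log: list[tuple[int, str]] = field(default_factory=list)
    terminal_history: dict[int, frozenset[str]] = field(default_factory=dict)
    planted_loops: list[tuple[int, str, str]] = field(default_factory=list)


def generate_map(params: GenParams) -> tuple[VegetationMap, SyntheticTruth]:
    """Generate a vegetation map (no used-edges yet) and its truth record.

    Topology: nodes uniform in the unit square, each joined to its 3
    nearest neighbors (guaranteeing degree >= 3), components stitched by
    nearest pairs; plants are connected graph-Voronoi territories grown by
    BFS from random seed junctions.  Edge lengths are log-uniform over the
    configured span (so the 100-fold spread holds regardless of layout);
    TI is 1 iff both edges of the transition belong to the same plant,
    else drawn from ``ti_probs_cross_plant``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    pos = rng.random((n, 2))
    node_ids = [f"n{i:03d}" for i in range(n)]

    # k-nearest-neighbor edges (k = degree_min)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        for j in np.argsort(d2[i])[: params.degree_min]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    g = nx.Graph(sorted(pairs))
    g.add_nodes_from(range(n))
    # stitch components by nearest cross-component pair
    comps = [sorted(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        best = None
        for a in comps[0]:
            for c in comps[1:]:
                for bnode in c:
                    key = (d2[a, bnode], a, bnode)
                    if best is None or key < best:
                        best = key
        _, a, bnode = best
        pairs.add((min(a, bnode), max(a, bnode)))
        g.add_edge(a, bnode)
        comps = [sorted(c) for c in nx.connected_components(g)]
    # top up any node still below the degree floor
    for i in range(n):
        k = params.degree_min
        while g.degree(i) < params.degree_min:
            for j in np.argsort(d2[i])[: k + 1]:
                j = int(j)
                if not g.has_edge(i, j):
                    pairs.add((min(i, j), max(i, j)))
                    g.add_edge(i, j)
                    break
            k += 1

    # plants: graph-Voronoi territories grown by multi-source BFS from
    # random seed junctions, so every plant is a connected subgraph of the
    # stem graph (a trail can run a long way on one plant, as field trails
    # do along a vine or branch)
    seeds = sorted(map(int, rng.choice(n, size=params.n_plants, replace=False)))
    plant_idx: dict[int, int] = {s: j for j, s in enumerate(seeds)}
    frontier = list(seeds)
    while frontier:
        nxt: list[int] = []
        for i in frontier:
            for j in sorted(g.neighbors(i)):
                if j not in plant_idx:
                    plant_idx[j] = plant_idx[i]
                    nxt.append(j)
        frontier = nxt
    plant_of = {node_ids[i]: f"p{plant_idx[i]:02d}" for i in range(n)}

    lo, hi = params.length_log10_range
    edge_list = sorted(pairs)
    lengths = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=len(edge_list))
    edges: dict[str, Edge] = {}
    for idx, ((i, j), ln) in enumerate(zip(edge_list, lengths)):
        eid = f"e{idx:04d}"
        edges[eid] = Edge(eid, node_ids[i], node_ids[j], float(ln))

    def edge_plant(e: Edge) -> str:
        # a stem belongs to one plant: that of its lexicographically first
        # junction (a boundary stem is part of the plant it grows from, so
        # crossing plants costs a single cross-plant transition, not two)
        return plant_of[min(e.u, e.v)]

    # transitions: one TI per unordered adjacent pair, mirrored to both orders
    incident: dict[str, list[str]] = {nid: [] for nid in node_ids}
    for e in edges.values():
        incident[e.u].append(e.edge_id)
        incident[e.v].append(e.edge_id)
    transitions: dict[tuple[str, str, str], int] = {}
    ti_choices = np.array([2, 3, 4])
    for v in node_ids:
        inc = sorted(incident[v])
        for a_i in range(len(inc)):
            for b_i in range(a_i + 1, len(inc)):
                ea, eb = edges[inc[a_i]], edges[inc[b_i]]
                if edge_plant(ea) == edge_plant(eb):
                    ti = 1
                else:
                    ti = int(rng.choice(ti_choices, p=params.ti_probs_cross_plant))
                transitions[(ea.edge_id, v, eb.edge_id)] = ti
                transitions[(eb.edge_id, v, ea.edge_id)] = ti

    # terminal schedule with turnover; the root terminal (main nest)
    # persists.  Nests and food sources are not arbitrary junctions: a
    # colony forages where it can maintain a coherent trail, so terminals
    # are drawn with probability decaying in the minimum transition-cost
    # (summed TI excess over 1) of a route from the root.
    lo_t, hi_t = params.n_terminals_per_day
    root = node_ids[int(rng.integers(n))]
    lg_simple = nx.Graph()
    for (ein, v, eout), ti in transitions.items():
        lg_simple.add_edge(ein, eout, w=ti - 1)
    ti_dist = nx.multi_source_dijkstra_path_length(
        lg_simple, sorted(incident[root]), weight="w"
    )
    root_i = node_ids.index(root)
    hops = nx.single_source_shortest_path_length(g, root_i)
    eligible: list[str] = []
    weights: list[float] = []
    for i, nid in enumerate(node_ids):
        if nid == root or hops.get(i, 10**9) < params.terminal_min_hops:
            continue
        cost = min((ti_dist[eid] for eid in incident[nid] if eid in ti_dist), default=None)
        if cost is None:
            continue
        eligible.append(nid)
        weights.append(float(np.exp(-cost / params.terminal_cost_scale)))
    warr = np.asarray(weights)
    warr = warr / warr.sum()

    def _draw_terminals(k: int, exclude: set[str]) -> list[str]:
        mask = np.asarray([nid not in exclude for nid in eligible])
        p = warr * mask
        k = min(k, int(mask.sum()))
        picks = rng.choice(len(eligible), size=k, replace=False, p=p / p.sum())
        return [eligible[int(i)] for i in picks]

    k0 = int(rng.integers(lo_t, hi_t + 1))
    terms = {root} | set(_draw_terminals(k0 - 1, {root}))
    days: list[DayRecord] = []
    truth = SyntheticTruth()
    for di in range(1, params.n_days + 1):
        if di > 1:
            kept = {root}
            for t in sorted(terms - {root}):
                if rng.random() >= params.terminal_turnover_prob:
                    kept.add(t)
            k_target = int(rng.integers(lo_t, hi_t + 1))
            if len(kept) < k_target:
                kept |= set(_draw_terminals(k_target - len(kept), kept))
            terms = kept
        days.append(DayRecord(di, frozenset(terms)))
        truth.terminal_history[di] = frozenset(terms)

    vmap = VegetationMap(
        nodes={nid: plant_of[nid] for nid in node_ids},
        edges=edges,
        transitions=transitions,
        days=days,
        root_terminal=root,
        colony=f"synthetic-{params.seed}",
        metadata={
            "generator": "trailnets.synth",
            "seed": params.seed,
            "orientation_rule": "bfs-from-root, ties toward larger node-id",
        },
    )
    return vmap, truth


def plant_observed_trails(
    vmap: VegetationMap, truth: SyntheticTruth, params: GenParams
) -> VegetationMap:
    """Fill each day's used-edges with a planted low-TI trail.

    The planted trail is the minimum-transition-cost route union for the
    day's terminals, plus exploration-noise spurs, plus (with probability
    ``loop_insertion_prob`` per day) one two-branch loop.  Between days,
    one used edge may rupture (probability ``rupture_prob``), becoming
    unavailable from the next day on; terminals stranded by a rupture are
    re-drawn.
    """
    rng = np.random.default_rng(params.seed + 1_000_003)
    days = list(vmap.days)
    new_days: list[DayRecord] = []
    pending_removed: frozenset[str] = frozenset()
    prev_used: frozenset[str] = frozenset()
    for day in days:
        day = replace(day, removed_edges=pending_removed)
        vmap.days = new_days + [day] + days[len(new_days) + 1 :]
        avail = vmap.available_edges(day.day_index)
        g = vmap.graph(edge_ids=avail)
        # re-draw terminals stranded by ruptures
        terms = set(day.terminals)
        root_comp = (
            set(nx.node_connected_component(g, vmap.root_terminal))
            if vmap.root_terminal in g
            else set()
        )
        stranded = sorted(t for t in terms if t not in root_comp)
        if stranded:
            logger.info(
                "day %d: terminals %s unreachable after rupture; re-drawing",
                day.day_index,
                stranded,
            )
            pool = sorted(root_comp - terms)
            for t in stranded:
                terms.discard(t)
                if pool:
                    pick = str(rng.choice(pool))
                    terms.add(pick)
                    pool.remove(pick)
            day = replace(day, terminals=frozenset(terms))
            truth.terminal_history[day.day_index] = frozenset(terms)

        used = _min_ti_path_union(vmap, day.day_index, sorted(terms))

        # exploration noise: spur edges off the planted trail
        if params.exploration_noise > 0:
            trail_nodes = sorted(
                {n for eid in used for n in vmap.edges[eid].endpoints}
            )
            for v in trail_nodes:
                if rng.random() < params.exploration_noise and v in g:
                    nbrs = sorted(g.neighbors(v))
                    if nbrs:
                        w = str(rng.choice(nbrs))
                        used.add(vmap.edge_between(v, w).edge_id)

        # loop insertion: add an alternative outbound branch
        if rng.random() < params.loop_insertion_prob:
            loop = _insert_loop(vmap, day.day_index, used, rng)
            if loop is not None:
                s, t, extra = loop
                used |= extra
                truth.planted_loops.append((day.day_index, s, t))

        day = replace(day, used_edges=frozenset(used))
        new_days.append(day)
        truth.planted_edges[day.day_index] = frozenset(used)
        prev_used = frozenset(used)

        # decide next day's rupture from this day's used set
        pending_removed = frozenset()
        if day.day_index < len(days) and rng.random() < params.rupture_prob:
            candidates = sorted(prev_used)
            rng.shuffle(candidates)
            already_gone = vmap.removed_through(day.day_index)
            for eid in candidates:
                remaining = (set(vmap.edges) - set(already_gone)) - {eid}
                h = vmap.graph(edge_ids=remaining)
                if h.number_of_nodes() and nx.is_connected(h):
                    pending_removed = frozenset({eid})
                    truth.rupture_log.append((day.day_index + 1, eid))
                    break

    vmap.days = new_days
    # planted objectives (after all days finalized)
    for day in vmap.days:
        net = network_from_edges(
            vmap, day.day_index, day.used_edges, "observed", extra_nodes=day.terminals
        )
        truth.planted_objectives[day.day_index] = compute_objectives(net, vmap)
    vmap.invalidate_caches()
    return vmap


def _min_ti_path_union(
    vmap: VegetationMap, day_index: int, terminals: list[str]
) -> set[str]:
    """Planted trail: union of minimum-transition-cost routes root->terminal.

    Routes are shortest paths on the outbound line graph with step cost
    ``ti - 1 + 0.05``: same-plant (TI 1) transitions are nearly free, so a
    route prefers a long run along one plant over a short hop across
    plants, with a mild per-transition penalty keeping routes compact.
    This is the trail structure the ants converge on: most readily
    reinforced transitions, few junctions.  Falls back to the undirected
    line graph for terminals unreachable in the outbound orientation.
    """
    from trailnets.core import to_line_graph

    root = vmap.root_terminal
    lg = to_line_graph(vmap, day_index).graph.copy()
    for _, _, d in lg.edges(data=True):
        d["step_cost"] = d["ti"] - 1 + 0.05
    incident: dict[str, list[str]] = {}
    for eid in lg.nodes:
        e = vmap.edges[eid]
        incident.setdefault(e.u, []).append(eid)
        incident.setdefault(e.v, []).append(eid)
    sources = sorted(incident.get(root, []))
    if not sources:
        raise MapError(f"root terminal {root} has no available edges")
    dist, paths = nx.multi_source_dijkstra(lg, sources, weight="step_cost")
    lg_und = lg.to_undirected(as_view=True)
    dist_u, paths_u = nx.multi_source_dijkstra(lg_und, sources, weight="step_cost")
    used: set[str] = set()
    for t in terminals:
        if t == root:
            continue
        cands = [eid for eid in incident.get(t, []) if eid in dist]
        if cands:
            best = min(cands, key=lambda eid: (dist[eid], eid))
            used.update(paths[best])
            continue
        cands = [eid for eid in incident.get(t, []) if eid in dist_u]
        if not cands:
            raise MapError(f"terminal {t} unreachable in line graph on day {day_index}")
        best = min(cands, key=lambda eid: (dist_u[eid], eid))
        used.update(paths_u[best])
    return used


def _insert_loop(
    vmap: VegetationMap,
    day_index: int,
    used: set[str],
    rng: np.random.Generator,
) -> Optional[tuple[str, str, frozenset[str]]]:
    """Try to add a second outbound branch between two trail nodes."""
    dg_used = outbound_digraph(vmap, edge_ids=used)
    dg_all = outbound_digraph(vmap, day_index)
    nodes = sorted(dg_used.nodes)
    rng.shuffle(nodes)
    for s in nodes[:20]:
        # walk 2-3 hops forward along the used trail
        for t in sorted(nx.descendants_at_distance(dg_used, s, 2) | nx.descendants_at_distance(dg_used, s, 3)):
            try:
                obs = next(iter(nx.all_simple_paths(dg_used, s, t, cutoff=3)))
            except StopIteration:
                continue
            interior = set(obs[1:-1])
            for alt in nx.all_simple_paths(dg_all, s, t, cutoff=4):
                if set(alt[1:-1]) & interior or set(alt[1:-1]) & set(dg_used.nodes):
                    continue
                extra = {
                    vmap.edge_between(a, b).edge_id for a, b in zip(alt, alt[1:])
                }
                if extra - used:
                    return s, t, frozenset(extra)
    return None


def generate_colony(params: GenParams) -> tuple[VegetationMap, SyntheticTruth]:
    """Generate a complete synthetic colony: map, days, and planted trails."""
    vmap, truth = generate_map(params)
    vmap = plant_observed_trails(vmap, truth, params)
    vmap.validate()
    return vmap, truth


def available_mean_ti(vmap: VegetationMap, day_index: Optional[int] = None) -> float:
    """Mean TI over all transition records among available edges (each
    unordered adjacent pair counted once)."""
    avail = vmap.available_edges(day_index)
    seen = set()
    vals = []
    for (ein, v, eout), ti in vmap.transitions.items():
        if ein in avail and eout in avail:
            key = (min(ein, eout), v, max(ein, eout))
            if key not in seen:
                seen.add(key)
                vals.append(ti)
    return float(np.mean(vals))
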