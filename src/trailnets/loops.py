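"""Loop detection, centered-rank analysis, and trail connectivity.

A loop is a pair of (two or more) outbound paths in a trail network that
start and end at the same source and target nodes.  Each observed loop path
is ranked among all simple outbound paths available in the vegetation
between the same source and target, by average transition index, node
count, and average edge length; the *centered rank* is the path's rank
minus the median rank (n+1)/2, so negative values mean the observed path
beats the median available alternative.

Connectivity measures how easily a lost ant rejoins the trail: for every
edge leading off the trail, the fewest-node return path from the off-trail
node back to the trail, averaged over all off-trail edges on all days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from trailnets.core import TrailNetwork, VegetationMap, outbound_digraph

logger = logging.getLogger(__name__)

LOOP_OBJECTIVES = ("avg_ti", "n_nodes", "avg_length")


@dataclass(frozen=True)
class LoopRecord:
    """One loop: a (source, target) pair with >= 2 disjoint outbound paths."""

    day_index: int
    source: str
    target: str
    observed_paths: tuple[tuple[str, ...], ...]
    candidate_paths: tuple[tuple[str, ...], ...] = ()
    centered_ranks: Optional[dict[str, float]] = None


def path_objectives(path: Sequence[str], vmap: VegetationMap) -> dict[str, Optional[float]]:
    """Average TI, node count and mean edge length of one outbound path."""
    edges = [vmap.edge_between(a, b) for a, b in zip(path, path[1:])]
    tis = []
    for (a, b), (c, d) in zip(zip(path, path[1:]), zip(path[1:], path[2:])):
        ein = vmap.edge_between(a, b).edge_id
        eout = vmap.edge_between(c, d).edge_id
        ti = vmap.transitions.get((ein, b, eout))
        if ti is not None:
            tis.append(ti)
    return {
        "avg_ti": sum(tis) / len(tis) if tis else None,
        "n_nodes": float(len(path)),
        "avg_length": sum(e.length for e in edges) / len(edges) if edges else None,
    }


def find_loops(
    network: TrailNetwork, vmap: VegetationMap, max_nodes: int = 12
) -> list[LoopRecord]:
    """Every (source, target) pair joined by >= 2 internally node-disjoint
    outbound used paths, reported once."""
    g = network.digraph(vmap)
    records: list[LoopRecord] = []
    sources = [n for n in g.nodes if g.out_degree(n) >= 2]
    targets = {n for n in g.nodes if g.in_degree(n) >= 2}
    for s in sorted(sources):
        for t in sorted(targets):
            if s == t:
                continue
            paths = [
                tuple(p)
                for p in nx.all_simple_paths(g, s, t, cutoff=max_nodes - 1)
            ]
            if len(paths) < 2:
                continue
            disjoint = _max_disjoint(paths)
            if len(disjoint) >= 2:
                records.append(LoopRecord(network.day_index, s, t, tuple(disjoint)))
    return records


def _max_disjoint(paths: list[tuple[str, ...]]) -> list[tuple[str, ...]]:
    """Greedy maximal set of internally node-disjoint paths (shortest first)."""
    chosen: list[tuple[str, ...]] = []
    used: set[str] = set()
    for p in sorted(paths, key=lambda p: (len(p), p)):
        interior = set(p[1:-1])
        if interior & used:
            continue
        chosen.append(p)
        used |= interior
    return chosen


def enumerate_candidate_paths(
    vmap: VegetationMap,
    source: str,
    target: str,
    day_index: Optional[int] = None,
    max_nodes: int = 12,
) -> list[tuple[str, ...]]:
    """All simple outbound paths from source to target in the available
    vegetation with at most ``max_nodes`` nodes.

    The default cutoff reflects the field-mapping margin of a few nodes
    beyond the trail; paths longer than the cutoff are not enumerated.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = outbound_digraph(vmap, day_index)
    if source not in g or target not in g:
        return []
    return [tuple(p) for p in nx.all_simple_paths(g, source, target, cutoff=max_nodes - 1)]


def centered_rank(
    observed: Sequence[str],
    candidates: Sequence[Sequence[str]],
    vmap: VegetationMap,
    objective: str,
) -> float:
    """Rank of the observed path among candidates minus the median rank.

    Candidates are ranked ascending by the objective (average rank for
    ties); the median rank of n candidates is (n+1)/2, so the centered rank
    is 0 for a median path and negative for a better-than-median one.
    """
    if objective not in LOOP_OBJECTIVES:
        raise ValueError(f"unknown loop objective {objective!r}")
    cands = [tuple(c) for c in candidates]
    obs = tuple(observed)
    if obs not in cands:
        raise ValueError("observed path is not among the candidate paths")
    scored = [
        (c, path_objectives(c, vmap)[objective]) for c in cands
    ]
    # paths too short to define the objective (e.g. no transitions) are
    # excluded from the ranking
    scored = [(c, v) for c, v in scored if v is not None]
    if obs not in [c for c, _ in scored]:
        raise ValueError(f"observed path has no defined {objective}")
    vals = np.asarray([v for _, v in scored], dtype=float)
    ranks = sps.rankdata(vals, method="average")
    n = len(scored)
    idx = [c for c, _ in scored].index(obs)
    return float(ranks[idx] - (n + 1) / 2.0)


def rank_loops(
    records: Iterable[LoopRecord],
    vmap: VegetationMap,
    max_nodes: int = 12,
) -> list[LoopRecord]:
    """Attach candidate paths and per-objective centered ranks to each loop.

    Each observed path of each loop contributes one centered rank per
    objective; the record stores the mean over its observed paths.
    """
    out: list[LoopRecord] = []
    for rec in records:
        cands = enumerate_candidate_paths(
            vmap, rec.source, rec.target, rec.day_index, max_nodes
        )
        cand_set = set(cands)
        for p in rec.observed_paths:
            if p not in cand_set:
                cands.append(p)  # observed path longer than cutoff: still ranked
        ranks: dict[str, float] = {}
        for obj in LOOP_OBJECTIVES:
            vals = []
            for p in rec.observed_paths:
                try:
                    vals.append(centered_rank(p, cands, vmap, obj))
                except ValueError:
                    continue  # path too short to score this objective
            if vals:
                ranks[obj] = float(np.mean(vals))
        out.append(
            LoopRecord(
                rec.day_index,
                rec.source,
                rec.target,
                rec.observed_paths,
                tuple(cands),
                ranks,
            )
        )
    return out


def loop_summary(records: Sequence[LoopRecord]) -> dict[str, dict[str, float]]:
    """Per-objective mean, SD and two-sided one-sample t test of the
    centered ranks against 0."""
    out: dict[str, dict[str, float]] = {}
    for obj in LOOP_OBJECTIVES:
        vals = np.asarray(
            [
                r.centered_ranks[obj]
                for r in records
                if r.centered_ranks and obj in r.centered_ranks
                and np.isfinite(r.centered_ranks[obj])
            ],
            dtype=float,
        )
        entry: dict[str, float] = {"n": float(vals.size)}
        if vals.size:
            entry["mean"] = float(vals.mean())
            entry["sd"] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        if vals.size >= 2 and np.ptp(vals) > 0:
            t, p = sps.ttest_1samp(vals, 0.0)
            entry["t"] = float(t)
            entry["p"] = float(p)
        out[obj] = entry
    return out


def connectivity(
    vmap: VegetationMap, networks: Sequence[TrailNetwork]
) -> tuple[float, int]:
    """Mean fewest-node return path from off-trail nodes back to the trail.

    For each day's network and each available edge (u, v) with u on the
    trail and v off it, the return path runs from v back to any trail node
    without re-using the edge (u, v); its node count includes v and the
    rejoining trail node.  Returns (average, number of off-trail edges
    counted); edges with no way back are excluded and logged.
    """
    counts: list[int] = []
    skipped = 0
    for net in networks:
        g = vmap.graph(net.day_index)
        trail = set(net.node_ids) & set(g.nodes)
        if not trail:
            continue
        for u in sorted(trail):
            for v in sorted(g.neighbors(u)):
                if v in trail:
                    continue
                h = g.copy()
                h.remove_edge(u, v)
                n = _fewest_node_return(h, v, trail)
                if n is None:
                    skipped += 1
                else:
                    counts.append(n)
    if skipped:
        logger.info("connectivity: %d off-trail edges had no return path", skipped)
    if not counts:
        raise ValueError("no off-trail edges with a return path")
    return float(np.mean(counts)), len(counts)


def _fewest_node_return(g: nx.Graph, start: str, trail: set[str]) -> Optional[int]:
    """BFS node count of the shortest path from start to any trail node,
    counting both start and the rejoining trail node."""
    if start not in g:
        return None
    seen = {start}
    frontier = [start]
    depth = 1
    while frontier:
        nxt = []
        for n in frontier:
            for m in g.neighbors(n):
                if m in trail:
                    return depth + 1
                if m not in seen:
                    seen.add(m)
                    nxt.append(m)
        frontier = nxt
        depth += 1
    return None
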