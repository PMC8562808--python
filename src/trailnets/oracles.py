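"""Exact brute-force solvers and the Hamiltonian-path reduction.

Minimizing the average transition index of a terminal-spanning subtree is
NP-complete; the hardness comes from the minimum average-weight path
problem, which is itself NP-complete by reduction from directed Hamiltonian
path.  The reduction augments a digraph G with a super-source s (edges of
weight 2 to every vertex) and super-sink t (weight-2 edges from every
vertex), with all original edges given weight 1; the smallest possible
average edge weight of an s-t path is (3+|V|)/(|V|+1), attained exactly
when the path threads a Hamiltonian path of G.

These solvers are exponential-time correctness oracles for the heuristics,
guarded by explicit instance-size limits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from trailnets.core import VegetationMap, to_line_graph


@dataclass(frozen=True)
class ReductionInstance:
    source: nx.DiGraph
    augmented: nx.DiGraph
    s: str = "__s__"
    t: str = "__t__"

    @property
    def threshold(self) -> float:
        n = self.source.number_of_nodes()
        return (3.0 + n) / (n + 1.0)


def build_reduction(g: nx.DiGraph) -> ReductionInstance:
    """Augment a simple digraph for the Hamiltonian-path reduction.

    Adds s and t (so |V'| = |V|+2 and |E'| = |E| + 2|V|): weight-1 original
    edges, weight-2 edges s->v and v->t for every original vertex v.
    """
    s, t = "__s__", "__t__"
    if s in g or t in g:
        raise ValueError("graph already contains reserved nodes __s__/__t__")
    aug = nx.DiGraph()
    aug.add_nodes_from(g.nodes)
    for u, v in g.edges:
        aug.add_edge(u, v, weight=1.0)
    for v in g.nodes:
        aug.add_edge(s, v, weight=2.0)
        aug.add_edge(v, t, weight=2.0)
    return ReductionInstance(g.copy(), aug)


def brute_min_avg_path(
    g: nx.DiGraph, u, v, weight: str = "weight"
) -> tuple[list, float]:
    """Exhaustive minimum average-weight simple path from u to v.

    The search is restricted to simple paths: allowing repeated nodes would
    let low-mean cycles drive the infimum to the minimum mean cycle and
    degenerate the decision problem.
    """
    best_path: Optional[list] = None
    best_avg = float("inf")
    for path in nx.all_simple_paths(g, u, v):
        w = [g.edges[a, b][weight] for a, b in zip(path, path[1:])]
        avg = sum(w) / len(w)
        if avg < best_avg - 1e-12:
            best_avg = avg
            best_path = path
    if best_path is None:
        raise ValueError(f"no path from {u!r} to {v!r}")
    return best_path, best_avg


def has_hamiltonian_path(g: nx.DiGraph) -> bool:
    """Brute-force directed Hamiltonian path existence (|V| <= 8)."""
    nodes = list(g.nodes)
    if len(nodes) > 8:
        raise ValueError("brute-force Hamiltonian check limited to |V| <= 8")
    if len(nodes) <= 1:
        return True
    for perm in itertools.permutations(nodes):
        if all(g.has_edge(a, b) for a, b in zip(perm, perm[1:])):
            return True
    return False


def verify_reduction(g: nx.DiGraph, tol: float = 1e-9) -> bool:
    """Check the reduction equivalence on one instance.

    True iff [G has a directed Hamiltonian path] agrees with [the minimum
    average-weight s-t path in the augmented graph is <= (3+|V|)/(|V|+1)].
    """
    inst = build_reduction(g)
    ham = has_hamiltonian_path(g)
    try:
        _, avg = brute_min_avg_path(inst.augmented, inst.s, inst.t)
    except ValueError:
        return not ham
    return ham == (avg <= inst.threshold + tol)


def _enumerate_subtrees(
    g: nx.Graph, max_edges: int
) -> Iterable[tuple[frozenset, list]]:
    edges = sorted(g.edges)
    for k in range(1, max_edges + 1):
        for combo in itertools.combinations(edges, k):
            sub = nx.Graph(combo)
            if sub.number_of_edges() == sub.number_of_nodes() - 1 and nx.is_connected(sub):
                yield frozenset(sub.nodes), list(combo)


def brute_min_avg_ti_subtree(
    vmap: VegetationMap,
    terminals: Sequence[str],
    day_index: Optional[int] = None,
    max_line_nodes: int = 12,
) -> tuple[list, float]:
    """Exact minimum-average-TI terminal-spanning subtree of the line graph.

    Exhaustive over connected acyclic line-edge subsets; a terminal is
    covered when the subtree contains a map edge incident to it.  Only for
    tiny instances (the problem is NP-complete); larger maps should use the
    greedy heuristic.
    """
    lg = to_line_graph(vmap, day_index).undirected()
    if lg.number_of_nodes() > max_line_nodes:
        raise ValueError(
            f"instance too large ({lg.number_of_nodes()} line-nodes > "
            f"{max_line_nodes}); use greedy_min_avg_ti"
        )
    X = set(terminals)

    def covered(line_nodes: Iterable[str]) -> bool:
        cov: set[str] = set()
        for eid in line_nodes:
            cov |= vmap.edges[eid].endpoints
        return X <= cov

    # a single map edge may already cover all terminals (no transitions)
    for eid in lg.nodes:
        if X <= vmap.edges[eid].endpoints:
            return [], 0.0

    best: Optional[tuple[list, float]] = None
    for nodes, combo in _enumerate_subtrees(lg, lg.number_of_edges()):
        if not covered(nodes):
            continue
        tis = [lg.edges[a, b]["ti"] for a, b in combo]
        avg = sum(tis) / len(tis)
        if best is None or avg < best[1] - 1e-12:
            best = ([tuple(sorted(e)) for e in combo], avg)
    if best is None:
        raise ValueError("no terminal-covering subtree exists")
    return best


def brute_min_avg_ti_network(
    vmap: VegetationMap,
    terminals: Sequence[str],
    day_index: Optional[int] = None,
    max_edges: int = 14,
) -> tuple[frozenset, float]:
    """Exact minimum realized-average-TI connected terminal-spanning network.

    Scores candidates exactly as :func:`trailnets.stats.compute_objectives`
    does — the mean TI over every activated outbound transition — by
    exhaustion over connected edge subsets.  Oracle for the greedy TI
    heuristic on tiny fixtures.
    """
    from trailnets.core import transitions_of

    eids = sorted(vmap.available_edges(day_index))
    if len(eids) > max_edges:
        raise ValueError(f"instance too large ({len(eids)} edges > {max_edges})")
    X = set(terminals)
    best: Optional[tuple[frozenset, float]] = None
    for k in range(1, len(eids) + 1):
        for combo in itertools.combinations(eids, k):
            sub = vmap.graph(edge_ids=combo)
            if not X <= set(sub.nodes) or not nx.is_connected(sub):
                continue
            trans = transitions_of(combo, vmap)
            if not trans:
                continue
            avg = sum(t[3] for t in trans) / len(trans)
            if best is None or avg < best[1] - 1e-12:
                best = (frozenset(combo), avg)
    if best is None:
        raise ValueError("no terminal-spanning network with transitions exists")
    return best


def brute_min_avg_length_network(
    vmap: VegetationMap,
    terminals: Sequence[str],
    day_index: Optional[int] = None,
    max_edges: int = 14,
) -> tuple[frozenset, float]:
    """Exact minimum-average-length connected terminal-spanning subgraph.

    Exhaustive over all connected edge subsets containing the terminals
    (not only trees: a cheap extra edge can lower the average).  Oracle for
    the greedy average-length heuristic on tiny fixtures.
    """
    g = vmap.graph(day_index)
    eids = sorted(vmap.available_edges(day_index))
    if len(eids) > max_edges:
        raise ValueError(f"instance too large ({len(eids)} edges > {max_edges})")
    X = set(terminals)
    best: Optional[tuple[frozenset, float]] = None
    for k in range(1, len(eids) + 1):
        for combo in itertools.combinations(eids, k):
            sub = vmap.graph(edge_ids=combo)
            if not X <= set(sub.nodes) or not nx.is_connected(sub):
                continue
            avg = sum(vmap.edges[e].length for e in combo) / k
            if best is None or avg < best[1] - 1e-12:
                best = (frozenset(combo), avg)
    if best is None:
        raise ValueError("no connected terminal-spanning subgraph exists")
    return best


def brute_min_total_nodes(
    vmap: VegetationMap,
    terminals: Sequence[str],
    day_index: Optional[int] = None,
    max_nodes: int = 12,
) -> int:
    """Exact minimum node count of a connected terminal-spanning subgraph
    (Steiner-tree optimum in node count), by enumeration over node subsets."""
    g = vmap.graph(day_index)
    if g.number_of_nodes() > max_nodes:
        raise ValueError(f"instance too large ({g.number_of_nodes()} nodes)")
    X = set(terminals)
    others = sorted(set(g.nodes) - X)
    for extra in range(0, len(others) + 1):
        for combo in itertools.combinations(others, extra):
            sub = g.subgraph(X | set(combo))
            if sub.number_of_nodes() and nx.is_connected(sub) and X <= set(sub.nodes):
                return sub.number_of_nodes()
    raise ValueError("terminals cannot be connected")
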