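"""Random trail-network null models.

Two ensembles of random networks connect the same terminals as the observed
trails:

* the *day-to-day dependent* model builds a random network for the first
  day by attaching uniform random walks terminal by terminal, then evolves
  it across days — walks to dropped terminals are retracted back to the
  first endpoint (node where another walk attached), walks to new terminals
  are added;
* the *day-to-day independent* model rebuilds a network from scratch every
  day.

Walks step uniformly over all incident edges of the current node on the
day's available subgraph, in either direction (stems are traversable both
ways), with backtracking allowed; a walk stops the first time it touches a
node already in the network.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from trailnets.core import MapError, TrailNetwork, VegetationMap, network_from_edges

logger = logging.getLogger(__name__)


class WalkError(MapError):
    pass


@dataclass(frozen=True)
class EnsembleSpec:
    """Size and reproducibility of a random-network ensemble.

    Field-scale analyses use n = 100,000; the desk default of 1,000 keeps the
    Monte-Carlo standard error of a percentile below ~1.6 points.
    """

    n_networks: int = 1000
    model: str = "independent"  # or "dependent"
    seed: int = 0
    max_walk_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.model not in ("dependent", "independent"):
            raise ValueError(f"unknown model {self.model!r}")


def _adjacency(vmap: VegetationMap, day_index: int) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {}
    for eid in sorted(vmap.available_edges(day_index)):
        e = vmap.edges[eid]
        adj.setdefault(e.u, []).append(e.v)
        adj.setdefault(e.v, []).append(e.u)
    return adj


def random_walk(
    adj: dict[str, list[str]],
    start: str,
    stop_set,
    rng: random.Random,
    max_steps: int = 10_000,
) -> list[str]:
    """Uniform random walk from ``start`` until first touching ``stop_set``.

    Each step chooses uniformly among the current node's neighbors on the
    available subgraph.  Walks exceeding ``max_steps`` are restarted (the
    restart is logged); this truncation does not change the hitting
    distribution conditional on absorption for connected graphs.
    """
    if start in stop_set:
        raise WalkError(f"walk start {start!r} already in stop set")
    restarts = 0
    while True:
        path = [start]
        cur = start
        append = path.append
        randrange = rng.randrange
        for _ in range(max_steps):
            nbrs = adj.get(cur)
            if not nbrs:
                raise WalkError(f"node {cur!r} has no available neighbors")
            cur = nbrs[randrange(len(nbrs))]
            append(cur)
            if cur in stop_set:
                return path
        restarts += 1
        if restarts > 100:
            raise WalkError(
                f"stop set unreachable from {start!r} (100 restarts exceeded)"
            )
        logger.debug("random walk from %s restarted (max_steps exceeded)", start)


@dataclass
class _Walk:
    terminal: Optional[str]  # None for a residual (retracted) segment
    path: list[str]


@dataclass
class RandomNetworkState:
    """Bookkeeping for one random network as a union of walks.

    ``endpoints`` collects, for every walk, the node at which it attached to
    the pre-existing network.  The first terminal added ("seed") has no walk.
    """

    seed_node: str
    walks: list[_Walk] = field(default_factory=list)
    endpoints: set[str] = field(default_factory=set)
    terminals: set[str] = field(default_factory=set)

    def node_set(self) -> set[str]:
        nodes = {self.seed_node} | set(self.terminals)
        for w in self.walks:
            nodes.update(w.path)
        return nodes

    def edge_ids(self, vmap: VegetationMap) -> set[str]:
        pair = vmap._pair_index()
        eids: set[str] = set()
        for w in self.walks:
            p = w.path
            for a, b in zip(p, p[1:]):
                eids.add(pair[frozenset((a, b))])
        return eids

    def to_network(self, vmap: VegetationMap, day_index: int, provenance: str) -> TrailNetwork:
        return network_from_edges(
            vmap,
            day_index,
            self.edge_ids(vmap),
            provenance,
            extra_nodes=self.node_set(),
            terminal_walks={
                w.terminal: tuple(w.path) for w in self.walks if w.terminal
            },
            endpoints=frozenset(self.endpoints),
        )

    def copy(self) -> "RandomNetworkState":
        return RandomNetworkState(
            self.seed_node,
            [_Walk(w.terminal, list(w.path)) for w in self.walks],
            set(self.endpoints),
            set(self.terminals),
        )


def initial_random_network(
    vmap: VegetationMap,
    day_index: int,
    rng: random.Random,
    max_walk_steps: int = 10_000,
    adj: Optional[dict[str, list[str]]] = None,
) -> RandomNetworkState:
    """Build a random network for one day, terminal by terminal.

    A random terminal seeds the network; each remaining terminal, in random
    order, is connected by a random walk that stops on first touching the
    network; all nodes and edges touched by the walk join the network.
    """
    if adj is None:
        adj = _adjacency(vmap, day_index)
    terminals = sorted(vmap.day(day_index).terminals)
    missing = [t for t in terminals if t not in adj]
    if missing:
        raise WalkError(f"terminals not on available subgraph: {missing}")
    rng.shuffle(terminals)
    state = RandomNetworkState(seed_node=terminals[0], terminals=set(terminals))
    net_nodes = {terminals[0]}
    for x in terminals[1:]:
        if x in net_nodes:
            # terminal already touched by an earlier walk: nothing to add
            state.endpoints.add(x)
            continue
        path = random_walk(adj, x, net_nodes, rng, max_walk_steps)
        state.walks.append(_Walk(x, path))
        state.endpoints.add(path[-1])
        net_nodes.update(path)
    return state


def evolve_random_network(
    prev: RandomNetworkState,
    vmap: VegetationMap,
    new_day_index: int,
    rng: random.Random,
    max_walk_steps: int = 10_000,
    adj: Optional[dict[str, list[str]]] = None,
) -> RandomNetworkState:
    """Day-to-day dependent update of a random network.

    For each dropped terminal, its stored walk is retracted: with e the
    first endpoint appearing in the walk, every node of the walk that is
    never touched at or after e's first occurrence is removed (the walk is
    truncated to the suffix starting at e).  For each added terminal a new
    random walk is attached.  Walks invalidated by an edge rupture are
    regenerated on the new availability.
    """
    if adj is None:
        adj = _adjacency(vmap, new_day_index)
    state = prev.copy()
    new_terms = set(vmap.day(new_day_index).terminals)
    missing = [t for t in sorted(new_terms) if t not in adj]
    if missing:
        raise WalkError(f"terminals not on available subgraph: {missing}")
    dropped = state.terminals - new_terms
    added = sorted(new_terms - state.terminals)

    # 1. retract walks of dropped terminals
    for w in state.walks:
        if w.terminal in dropped:
            idx = next(
                (i for i, n in enumerate(w.path) if n in state.endpoints),
                len(w.path) - 1,
            )
            w.path = w.path[idx:]
            w.terminal = None
    state.walks = [w for w in state.walks if len(w.path) > 1 or w.terminal]
    state.terminals = set(new_terms)

    # 2. drop walks broken by ruptures (terminal walks regenerate below)
    broken_terminals: list[str] = []
    kept: list[_Walk] = []
    for w in state.walks:
        ok = all(b in adj.get(a, ()) for a, b in zip(w.path, w.path[1:]))
        if ok:
            kept.append(w)
        elif w.terminal is not None:
            logger.debug("walk of terminal %s broken by rupture; regenerating", w.terminal)
            broken_terminals.append(w.terminal)
        else:
            logger.debug("residual segment broken by rupture; dropped")
    state.walks = kept

    # 3. attach walks for new (and rupture-broken) terminals
    net_nodes = state.node_set()
    if state.seed_node not in adj and state.walks:
        # seed junction itself lost all edges; re-anchor on an existing walk
        state.seed_node = state.walks[0].path[-1]
        net_nodes = state.node_set()
    for x in added + sorted(broken_terminals):
        if x in net_nodes:
            state.endpoints.add(x)
            continue
        path = random_walk(adj, x, net_nodes, rng, max_walk_steps)
        state.walks.append(_Walk(x, path))
        state.endpoints.add(path[-1])
        net_nodes.update(path)

    # 4. repair: ruptures may have disconnected pieces; re-walk any terminal
    #    no longer attached to the seed component
    _repair_connectivity(state, vmap, adj, rng, max_walk_steps)
    return state


def _repair_connectivity(
    state: RandomNetworkState,
    vmap: VegetationMap,
    adj: dict[str, list[str]],
    rng: random.Random,
    max_walk_steps: int,
) -> None:
    g = nx.Graph()
    g.add_node(state.seed_node)
    for w in state.walks:
        nx.add_path(g, w.path)
    comp = set(nx.node_connected_component(g, state.seed_node))
    loose = sorted(t for t in state.terminals if t not in comp)
    for x in loose:
        if x in comp:
            continue
        logger.debug("terminal %s disconnected after rupture; re-walking", x)
        path = random_walk(adj, x, comp, rng, max_walk_steps)
        state.walks.append(_Walk(x, path))
        state.endpoints.add(path[-1])
        comp.update(path)


def generate_ensemble(
    vmap: VegetationMap, spec: EnsembleSpec
) -> dict[int, list[TrailNetwork]]:
    """Generate a full random-network ensemble for every observation day.

    Returns ``{day_index: [TrailNetwork, ...]}`` with ``spec.n_networks``
    networks per day.  Dependent-model members are chained across days;
    independent-model members are drawn from scratch each day.  The result
    is reproducible from ``spec.seed``.
    """
    days = [d.day_index for d in vmap.days]
    adjs = {di: _adjacency(vmap, di) for di in days}
    out: dict[int, list[TrailNetwork]] = {di: [] for di in days}
    master = random.Random(spec.seed)
    provenance = f"random-{spec.model}"
    for _ in range(spec.n_networks):
        rng = random.Random(master.getrandbits(63))
        if spec.model == "independent":
            for di in days:
                st = initial_random_network(vmap, di, rng, spec.max_walk_steps, adjs[di])
                out[di].append(st.to_network(vmap, di, provenance))
        else:
            st = initial_random_network(vmap, days[0], rng, spec.max_walk_steps, adjs[days[0]])
            out[days[0]].append(st.to_network(vmap, days[0], provenance))
            for di in days[1:]:
                st = evolve_random_network(st, vmap, di, rng, spec.max_walk_steps, adjs[di])
                out[di].append(st.to_network(vmap, di, provenance))
    return out
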