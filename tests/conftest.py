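"""Shared fixtures: hand-built toy maps and tiny random maps.

Toy maps intentionally violate the field's degree >= 3 invariant (they are
minimal constructions for exercising single operations), so tests build
them with ``build_map`` and never call ``VegetationMap.validate``.
"""

from __future__ import annotations

import random

import pytest

from trailnets.core import DayRecord, Edge, VegetationMap
from trailnets.synth import GenParams, generate_colony


def build_map(
    edges: dict[str, tuple[str, str, float]],
    root: str,
    days: list[DayRecord] | None = None,
    transitions: dict[tuple[str, str, str], int] | None = None,
    default_ti: int = 1,
    plants: dict[str, str] | None = None,
) -> VegetationMap:
    """Construct a map from ``{edge_id: (u, v, length)}``.

    Transition records are auto-filled with ``default_ti`` for every
    ordered adjacent pair not given explicitly; explicit entries are
    mirrored to the reverse order unless the reverse is also explicit.
    """
    edge_objs = {eid: Edge(eid, u, v, ln) for eid, (u, v, ln) in edges.items()}
    nodes: dict[str, str | None] = {}
    for e in edge_objs.values():
        nodes.setdefault(e.u, (plants or {}).get(e.u))
        nodes.setdefault(e.v, (plants or {}).get(e.v))
    incident: dict[str, list[str]] = {}
    for e in edge_objs.values():
        incident.setdefault(e.u, []).append(e.edge_id)
        incident.setdefault(e.v, []).append(e.edge_id)
    trans: dict[tuple[str, str, str], int] = {}
    given = transitions or {}
    for v, inc in incident.items():
        for a in inc:
            for b in inc:
                if a == b:
                    continue
                key = (a, v, b)
                if key in given:
                    trans[key] = given[key]
                elif (b, v, a) in given:
                    trans[key] = given[(b, v, a)]
                else:
                    trans[key] = default_ti
    return VegetationMap(
        nodes=nodes,
        edges=edge_objs,
        transitions=trans,
        days=days or [DayRecord(1, frozenset({root}))],
        root_terminal=root,
        colony="toy",
    )


def random_tiny_map(
    rng: random.Random,
    n_nodes: int = 7,
    max_edges: int = 12,
    n_terminals: int = 3,
) -> VegetationMap:
    """Small random connected map with random lengths and TIs, for
    comparing heuristics against exhaustive oracles."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    pairs: set[tuple[str, str]] = set()
    # random spanning tree first, then extra edges
    order = nodes[:]
    rng.shuffle(order)
    for i in range(1, len(order)):
        a = order[rng.randrange(i)]
        pairs.add(tuple(sorted((a, order[i]))))
    while len(pairs) < max_edges:
        a, b = rng.sample(nodes, 2)
        pairs.add(tuple(sorted((a, b))))
    edges = {
        f"e{i}": (u, v, round(rng.uniform(1.0, 100.0), 2))
        for i, (u, v) in enumerate(sorted(pairs))
    }
    # random TIs per unordered adjacent pair
    edge_objs = {eid: Edge(eid, u, v, ln) for eid, (u, v, ln) in edges.items()}
    incident: dict[str, list[str]] = {}
    for e in edge_objs.values():
        incident.setdefault(e.u, []).append(e.edge_id)
        incident.setdefault(e.v, []).append(e.edge_id)
    trans: dict[tuple[str, str, str], int] = {}
    for v, inc in sorted(incident.items()):
        for i in range(len(inc)):
            for j in range(i + 1, len(inc)):
                ti = rng.randint(1, 4)
                trans[(inc[i], v, inc[j])] = ti
                trans[(inc[j], v, inc[i])] = ti
    terminals = frozenset(rng.sample(nodes, n_terminals))
    root = sorted(terminals)[0]
    return VegetationMap(
        nodes={n: None for n in nodes},
        edges=edge_objs,
        transitions=trans,
        days=[DayRecord(1, terminals)],
        root_terminal=root,
        colony="tiny",
    )


@pytest.fixture(scope="session")
def default_colony():
    """One synthetic colony at generator defaults (seed 1)."""
    vmap, truth = generate_colony(GenParams(seed=1))
    return vmap, truth


@pytest.fixture(scope="session")
def small_colony():
    """A smaller, faster synthetic colony for structural tests."""
    vmap, truth = generate_colony(
        GenParams(seed=3, n_nodes=60, n_plants=12, n_days=4)
    )
    return vmap, truth
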