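"""Graph model: orientation, line graph, observed networks, I/O."""

import pytest

from trailnets.core import (
    DayRecord,
    MapError,
    VegetationMap,
    adjacent_pairs_line_graph,
    observed_network,
    orient_outbound,
    outbound_digraph,
    to_line_graph,
    transitions_of,
)
from trailnets.synth import GenParams, generate_map

from conftest import build_map


# ----------------------------------------------------------------------
# orientation
# ----------------------------------------------------------------------
class TestOrientOutbound:
    def test_star_points_away_from_root(self):
        m = build_map(
            {"e1": ("N", "a", 1.0), "e2": ("N", "b", 1.0)}, root="N"
        )
        orient = orient_outbound(m)
        assert orient == {"e1": ("N", "a"), "e2": ("N", "b")}

    def test_path_chains_outbound(self):
        m = build_map({"e1": ("N", "a", 1.0), "e2": ("a", "b", 1.0)}, root="N")
        orient = orient_outbound(m)
        assert orient["e1"] == ("N", "a")
        assert orient["e2"] == ("a", "b")

    def test_equal_hop_tie_broken_toward_larger_id(self):
        # a and b are both 1 hop from root; the a-b edge must get exactly
        # one direction, toward the larger node-id
        m = build_map(
            {
                "e1": ("N", "a", 1.0),
                "e2": ("N", "b", 1.0),
                "e3": ("a", "b", 1.0),
            },
            root="N",
        )
        orient = orient_outbound(m)
        assert orient["e3"] == ("a", "b")

    def test_idempotent_and_single_direction(self, small_colony):
        vmap, _ = small_colony
        o1 = orient_outbound(vmap)
        o2 = orient_outbound(vmap)
        assert o1 is o2  # cached
        assert set(o1) == set(vmap.edges)
        for eid, (t, h) in o1.items():
            assert {t, h} == set(vmap.edges[eid].endpoints)

    def test_orphan_nodes_rejected(self):
        m = build_map(
            {"e1": ("N", "a", 1.0), "e2": ("x", "y", 1.0)}, root="N"
        )
        with pytest.raises(MapError, match="no path to root"):
            orient_outbound(m)


# ----------------------------------------------------------------------
# line graph
# ----------------------------------------------------------------------
class TestLineGraph:
    def test_directed_path_two_nodes_one_edge(self):
        m = build_map({"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0)}, root="a")
        lg = to_line_graph(m)
        assert lg.n_line_nodes == 2
        assert lg.n_line_edges == 1
        assert lg.graph.has_edge("e1", "e2")

    def test_two_in_two_out_gives_four_line_edges_through_node(self):
        # u1,u2 one hop from root feed v; v feeds w1,w2: 2 in x 2 out = 4
        m = build_map(
            {
                "r1": ("R", "u1", 1.0),
                "r2": ("R", "u2", 1.0),
                "a": ("u1", "v", 1.0),
                "b": ("u2", "v", 1.0),
                "c": ("v", "w1", 1.0),
                "d": ("v", "w2", 1.0),
            },
            root="R",
        )
        lg = to_line_graph(m)
        through_v = [
            (a, b) for a, b, d in lg.graph.edges(data=True) if d["node"] == "v"
        ]
        assert sorted(through_v) == [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]

    def test_three_edge_toy_wiring(self):
        # path x-y-z-w: transitions chain the consecutive edges only
        m = build_map(
            {"e1": ("x", "y", 1.0), "e2": ("y", "z", 1.0), "e3": ("z", "w", 1.0)},
            root="x",
        )
        lg = to_line_graph(m)
        assert sorted(lg.graph.edges) == [("e1", "e2"), ("e2", "e3")]

    def test_weights_copied_from_ti(self):
        m = build_map(
            {"e1": ("x", "y", 1.0), "e2": ("y", "z", 1.0)},
            root="x",
            transitions={("e1", "y", "e2"): 3},
        )
        lg = to_line_graph(m)
        assert lg.graph.edges["e1", "e2"]["ti"] == 3

    def test_missing_transition_record_named(self):
        m = build_map({"e1": ("x", "y", 1.0), "e2": ("y", "z", 1.0)}, root="x")
        del m.transitions[("e1", "y", "e2")]
        with pytest.raises(MapError, match="e1.*y.*e2"):
            to_line_graph(m)

    def test_size_law_under_edge_removal(self, small_colony):
        """Removing availability never grows the line graph."""
        vmap, _ = small_colony
        full = to_line_graph(vmap, vmap.days[0].day_index)
        for day in vmap.days[1:]:
            lg = to_line_graph(vmap, day.day_index)
            assert lg.n_line_nodes <= full.n_line_nodes
            assert lg.n_line_edges <= full.n_line_edges
        # line-edge count == outbound transition count on available edges
        for day in vmap.days:
            lg = to_line_graph(vmap, day.day_index)
            trans = transitions_of(vmap.available_edges(day.day_index), vmap)
            assert lg.n_line_edges == len(trans)

    def test_adjacent_pairs_graph_connected_when_map_is(self, small_colony):
        import networkx as nx

        vmap, _ = small_colony
        lg = adjacent_pairs_line_graph(vmap, 1)
        assert nx.is_connected(lg)


# ----------------------------------------------------------------------
# transitions_of
# ----------------------------------------------------------------------
class TestTransitionsOf:
    def test_single_edge_has_none(self):
        m = build_map({"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0)}, root="a")
        assert transitions_of({"e1"}, m) == []

    def test_outbound_path_of_three_edges_has_two(self):
        m = build_map(
            {"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0), "e3": ("c", "d", 1.0)},
            root="a",
        )
        trans = transitions_of({"e1", "e2", "e3"}, m)
        assert [(t[0], t[1], t[2]) for t in trans] == [
            ("e1", "b", "e2"),
            ("e2", "c", "e3"),
        ]

    def test_y_junction_counts_both_branches(self):
        m = build_map(
            {
                "ein": ("r", "j", 1.0),
                "out1": ("j", "x", 1.0),
                "out2": ("j", "y", 1.0),
            },
            root="r",
        )
        trans = transitions_of({"ein", "out1", "out2"}, m)
        assert sorted((t[0], t[2]) for t in trans if t[1] == "j") == [
            ("ein", "out1"),
            ("ein", "out2"),
        ]


# ----------------------------------------------------------------------
# observed networks
# ----------------------------------------------------------------------
class TestObservedNetwork:
    def test_materializes_used_edges(self):
        days = [DayRecord(1, frozenset({"a", "d"}), frozenset({"e1", "e2", "e3"}))]
        m = build_map(
            {
                "e1": ("a", "b", 1.0),
                "e2": ("b", "c", 1.0),
                "e3": ("c", "d", 1.0),
                "e4": ("a", "c", 1.0),
            },
            root="a",
            days=days,
        )
        net = observed_network(m, 1)
        assert net.edge_ids == frozenset({"e1", "e2", "e3"})
        assert net.provenance == "observed"

    def test_empty_used_set_is_an_error(self):
        m = build_map({"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0)}, root="a")
        with pytest.raises(MapError, match="no observed network"):
            observed_network(m, 1)

    def test_used_removed_conflict_rejected(self):
        days = [
            DayRecord(1, frozenset({"a"}), frozenset({"e1"}), frozenset({"e2"})),
            DayRecord(2, frozenset({"a"}), frozenset({"e2"})),
        ]
        m = build_map(
            {"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0)}, root="a", days=days
        )
        with pytest.raises(MapError, match="removed"):
            observed_network(m, 2)

    def test_planted_edges_within_availability(self, default_colony):
        vmap, truth = default_colony
        for day in vmap.days:
            net = observed_network(vmap, day.day_index)
            assert net.edge_ids <= vmap.available_edges(day.day_index)
            assert net.edge_ids == truth.planted_edges[day.day_index]


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
class TestIO:
    def test_json_round_trip(self, small_colony):
        vmap, _ = small_colony
        doc = vmap.to_json()
        back = VegetationMap.from_json(doc)
        assert back.to_json() == doc
        assert back.edges.keys() == vmap.edges.keys()
        assert back.transitions == vmap.transitions
        assert [d.terminals for d in back.days] == [d.terminals for d in vmap.days]

    def test_csv_round_trip(self, small_colony):
        vmap, _ = small_colony
        files = vmap.to_csv()
        back = VegetationMap.from_csv(
            files["edges.csv"],
            files["transitions.csv"],
            files["days.csv"],
            root_terminal=vmap.root_terminal,
            nodes_csv=files["nodes.csv"],
        )
        assert back.edges.keys() == vmap.edges.keys()
        assert back.transitions == vmap.transitions
        assert back.edges["e0000"].length == vmap.edges["e0000"].length

    def test_graphml_export_parses(self, small_colony):
        import io

        import networkx as nx

        vmap, _ = small_colony
        text = vmap.to_graphml(day_index=1)
        g = nx.read_graphml(io.BytesIO(text.encode()))
        assert g.number_of_edges() == len(vmap.available_edges(1))


def test_availability_is_cumulative():
    days = [
        DayRecord(1, frozenset({"a"})),
        DayRecord(2, frozenset({"a"}), removed_edges=frozenset({"e1"})),
        DayRecord(3, frozenset({"a"})),
    ]
    m = build_map(
        {"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0), "e3": ("a", "c", 1.0)},
        root="a",
        days=days,
    )
    assert "e1" in m.available_edges(1)
    assert "e1" not in m.available_edges(2)
    assert "e1" not in m.available_edges(3)


def test_outbound_digraph_edges_match_orientation(small_colony):
    vmap, _ = small_colony
    orient = orient_outbound(vmap)
    dg = outbound_digraph(vmap, 1)
    for t, h, d in dg.edges(data=True):
        assert orient[d["edge_id"]] == (t, h)
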