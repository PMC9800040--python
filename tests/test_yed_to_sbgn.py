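import math

import pytest

from ysbgn.fixtures import fig2_fixtures, random_process_graph
from ysbgn.pd_model import (
    Arc,
    ArcClass,
    BBox,
    GlyphClass,
    Orientation,
    PDMap,
    Point,
    validate,
)
from ysbgn.yed_model import (
    ArrowType,
    YedEdge,
    YedEdgeStyle,
    YedGraph,
    YedNode,
    YedNodeStyle,
)
from ysbgn.yed_to_sbgn import (
    DegenerateProcessError,
    Reversibility,
    Side,
    arc_anchor,
    assign_ports_irreversible,
    assign_ports_reversible,
    classify_reversibility,
    compute_orientation,
    convert,
    detect_clones,
    find_aux_parent,
    parse_state_label,
    port_positions,
)


def _arc(aid: str, cls: ArcClass, src="E", tgt="P") -> Arc:
    return Arc(id=aid, cls=cls, source=src, target=tgt)


class TestClassifyReversibility:
    def test_mixed_flux_is_irreversible(self):
        arcs = [_arc("a", ArcClass.CONSUMPTION), _arc("b", ArcClass.CONSUMPTION),
                _arc("c", ArcClass.PRODUCTION)]
        assert classify_reversibility(arcs) is Reversibility.IRREVERSIBLE

    def test_all_production_is_reversible(self):
        arcs = [_arc("a", ArcClass.PRODUCTION), _arc("b", ArcClass.PRODUCTION)]
        assert classify_reversibility(arcs) is Reversibility.REVERSIBLE

    def test_modulation_arcs_ignored(self):
        arcs = [_arc("a", ArcClass.PRODUCTION), _arc("b", ArcClass.CATALYSIS)]
        assert classify_reversibility(arcs) is Reversibility.REVERSIBLE

    def test_all_consumption_is_degenerate(self):
        with pytest.raises(DegenerateProcessError):
            classify_reversibility([_arc("a", ArcClass.CONSUMPTION)])

    def test_no_flux_arcs_is_degenerate(self):
        with pytest.raises(DegenerateProcessError):
            classify_reversibility([_arc("a", ArcClass.INHIBITION)])


class TestArcAnchor:
    BOX = BBox(-10.0, -10.0, 20.0, 20.0)  # center (0, 0)
    PORTS = (Point(-20.0, 0.0), Point(20.0, 0.0))

    def _anchor(self, point: Point):
        arc = _arc("a", ArcClass.PRODUCTION, src="P", tgt="E")
        return arc_anchor(arc, "P", self.BOX, point, self.PORTS)

    def test_dominant_dx_gives_left(self):
        assert self._anchor(Point(-50.0, 5.0)).side is Side.LEFT

    def test_dominant_dy_gives_top(self):
        assert self._anchor(Point(0.0, -40.0)).side is Side.TOP

    def test_diagonal_tie_prefers_horizontal(self):
        assert self._anchor(Point(30.0, 30.0)).side is Side.RIGHT

    def test_distances_are_euclidean(self):
        anc = self._anchor(Point(-50.0, 0.0))
        assert anc.d_port1 == pytest.approx(30.0)
        assert anc.d_port2 == pytest.approx(70.0)

    def test_bend_adjacent_to_process_end_wins_over_endpoint(self):
        arc = Arc(id="a", cls=ArcClass.PRODUCTION, source="P", target="E",
                  bends=[Point(-30.0, 0.0), Point(-60.0, 10.0)])
        anc = arc_anchor(arc, "P", self.BOX, Point(999.0, 0.0), self.PORTS)
        assert anc.point == Point(-30.0, 0.0)  # first bend: process is the source

    def test_last_bend_used_when_process_is_target(self):
        arc = Arc(id="a", cls=ArcClass.CONSUMPTION, source="E", target="P",
                  bends=[Point(-60.0, 10.0), Point(-30.0, 0.0)])
        anc = arc_anchor(arc, "P", self.BOX, Point(999.0, 0.0), self.PORTS)
        assert anc.point == Point(-30.0, 0.0)


class TestComputeOrientation:
    def _anchors(self, sides):
        return [
            arc_anchor(_arc(f"a{i}", ArcClass.PRODUCTION, src="P"), "P",
                       TestArcAnchor.BOX, point, TestArcAnchor.PORTS)
            for i, point in enumerate(sides)
        ]

    def test_left_right_majority_is_horizontal(self):
        anchors = self._anchors([Point(-50, 0), Point(50, 5), Point(-40, 3)])
        assert compute_orientation(anchors) is Orientation.HORIZONTAL

    def test_top_bottom_majority_is_vertical(self):
        anchors = self._anchors([Point(0, -50), Point(5, 50), Point(3, -40)])
        assert compute_orientation(anchors) is Orientation.VERTICAL

    def test_tie_keeps_horizontal_assumption(self):
        anchors = self._anchors([Point(-50, 0), Point(0, -50)])
        assert compute_orientation(anchors) is Orientation.HORIZONTAL


class TestPortPositions:
    def test_horizontal_ports_sit_outside_left_right_midpoints(self):
        p1, p2 = port_positions(BBox(100, 100, 20, 20), Orientation.HORIZONTAL, antenna=10.0)
        assert p1 == Point(90.0, 110.0)
        assert p2 == Point(130.0, 110.0)

    def test_vertical_ports_sit_outside_top_bottom_midpoints(self):
        p1, p2 = port_positions(BBox(100, 100, 20, 20), Orientation.VERTICAL, antenna=10.0)
        assert p1 == Point(110.0, 90.0)
        assert p2 == Point(110.0, 130.0)


def _make_anchors(points_by_arc, ports, box=None):
    box = box or TestArcAnchor.BOX
    out = {}
    for aid, (cls, point) in points_by_arc.items():
        arc = _arc(aid, cls, src="P")
        out[aid] = arc_anchor(arc, "P", box, point, ports)
    return out, [_arc(aid, cls, src="P") for aid, (cls, _p) in points_by_arc.items()]


class TestAssignIrreversible:
    PORTS = (Point(-20.0, 0.0), Point(20.0, 0.0))

    def test_majority_consumption_side_honored(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.CONSUMPTION, Point(-50, 0)),
                "a2": (ArcClass.CONSUMPTION, Point(-60, 5)),
                "a3": (ArcClass.PRODUCTION, Point(40, 0)),
            },
            self.PORTS,
        )
        pa = assign_ports_irreversible("P", anchors, arcs, Orientation.HORIZONTAL, Point(0, 0))
        assert pa.port1_arcs == ["a1", "a2"]
        assert pa.port2_arcs == ["a3"]
        assert not pa.reversible and pa.repairs == 0

    def test_consumption_on_right_when_drawn_right(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.CONSUMPTION, Point(50, 0)),
                "a2": (ArcClass.PRODUCTION, Point(-40, 0)),
            },
            self.PORTS,
        )
        pa = assign_ports_irreversible("P", anchors, arcs, Orientation.HORIZONTAL, Point(0, 0))
        assert pa.port1_arcs == ["a2"]  # production takes the left port
        assert pa.port2_arcs == ["a1"]

    def test_tie_puts_consumption_left(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.CONSUMPTION, Point(-50, 0)),
                "a2": (ArcClass.CONSUMPTION, Point(50, 0)),
                "a3": (ArcClass.PRODUCTION, Point(-40, 10)),
            },
            self.PORTS,
        )
        pa = assign_ports_irreversible("P", anchors, arcs, Orientation.HORIZONTAL, Point(0, 0))
        assert set(pa.port1_arcs) == {"a1", "a2"}
        assert pa.port2_arcs == ["a3"]


class TestAssignReversible:
    PORTS = (Point(-12.0, 0.0), Point(12.0, 0.0))

    def test_nearest_port_wins_without_repair(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.PRODUCTION, Point(-50, 0)),
                "a2": (ArcClass.PRODUCTION, Point(-60, 5)),
                "a3": (ArcClass.PRODUCTION, Point(40, 0)),
            },
            self.PORTS,
        )
        pa = assign_ports_reversible("P", anchors, arcs, Orientation.HORIZONTAL)
        assert pa.port1_arcs == ["a1", "a2"]
        assert pa.port2_arcs == ["a3"]
        assert pa.repairs == 0

    def test_empty_port_repaired_by_moving_farthest_arc(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.PRODUCTION, Point(-50, 0)),
                "a2": (ArcClass.PRODUCTION, Point(-60, 0)),
                "a3": (ArcClass.PRODUCTION, Point(-70, 0)),
            },
            self.PORTS,
        )
        pa = assign_ports_reversible("P", anchors, arcs, Orientation.HORIZONTAL)
        assert pa.port2_arcs == ["a3"]  # the farthest from the occupied left port
        assert sorted(pa.port1_arcs) == ["a1", "a2"]
        assert pa.repairs == 1

    def test_equidistant_arcs_tie_break_then_repair(self):
        anchors, arcs = _make_anchors(
            {
                "a1": (ArcClass.PRODUCTION, Point(0, 30)),
                "a2": (ArcClass.PRODUCTION, Point(0, 40)),
            },
            self.PORTS,
        )
        pa = assign_ports_reversible("P", anchors, arcs, Orientation.HORIZONTAL)
        # both equidistant -> both initially on port 1; farthest (a2) moves
        assert pa.port1_arcs == ["a1"]
        assert pa.port2_arcs == ["a2"]
        assert pa.repairs == 1

    def test_single_arc_is_degenerate(self):
        anchors, arcs = _make_anchors(
            {"a1": (ArcClass.PRODUCTION, Point(-50, 0))}, self.PORTS
        )
        with pytest.raises(DegenerateProcessError):
            assign_ports_reversible("P", anchors, arcs, Orientation.HORIZONTAL)


class TestDetectClones:
    def _pool(self, pd, gid, label, comp=None, **kw):
        from ysbgn.pd_model import Glyph
        pd.add_glyph(Glyph(id=gid, cls=GlyphClass.SIMPLE_CHEMICAL,
                           bbox=BBox(0, 0, 60, 40), label=label, compartment_ref=comp, **kw))

    def test_same_label_same_compartment_marked(self):
        pd = PDMap()
        from ysbgn.pd_model import Glyph
        pd.add_glyph(Glyph(id="c", cls=GlyphClass.COMPARTMENT, bbox=BBox(0, 0, 500, 500)))
        self._pool(pd, "a", "ATP", comp="c")
        self._pool(pd, "b", "ATP", comp="c")
        assert detect_clones(pd) == {"a", "b"}

    def test_different_compartments_not_marked_under_default_policy(self):
        pd = PDMap()
        from ysbgn.pd_model import Glyph
        pd.add_glyph(Glyph(id="cy", cls=GlyphClass.COMPARTMENT, bbox=BBox(0, 0, 500, 500)))
        pd.add_glyph(Glyph(id="mi", cls=GlyphClass.COMPARTMENT, bbox=BBox(600, 0, 500, 500)))
        self._pool(pd, "a", "ATP", comp="cy")
        self._pool(pd, "b", "ATP", comp="mi")
        assert detect_clones(pd) == set()
        assert detect_clones(pd, per_compartment=False) == {"a", "b"}

    def test_singleton_not_marked(self):
        pd = PDMap()
        self._pool(pd, "a", "Glucose")
        assert detect_clones(pd) == set()

    def test_multimer_cardinality_splits_groups(self):
        pd = PDMap()
        self._pool(pd, "a", "ATP")
        self._pool(pd, "b", "ATP", multimer_cardinality=2)
        assert detect_clones(pd) == set()


class TestAuxAttachment:
    def test_state_label_parsing(self):
        assert parse_state_label("P@Ser15") == ("P", "Ser15")
        assert parse_state_label("P") == ("P", None)
        assert parse_state_label(None) == (None, None)

    def test_aux_ref_attachment(self):
        g = YedGraph()
        parent = YedNode(id="m", geometry=BBox(0, 0, 80, 40),
                         style=YedNodeStyle(configuration="com.yworks.sbgn.Macromolecule"),
                         label="p53", aux_refs=["sv1"])
        g.add_node(parent)
        g.add_node(YedNode(id="sv1", geometry=BBox(10, -7, 24, 14),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.StateVariable"),
                           label="P@Ser15"))
        pd, report = convert(g)
        sv = pd.glyphs["sv1"]
        assert sv.parent == "m"
        assert sv.state == ("P", "Ser15")
        assert pd.glyphs["m"].children == ["sv1"]
        assert not report.has_errors

    def test_geometric_fallback_attaches_overlapping_unit(self):
        g = YedGraph()
        g.add_node(YedNode(id="m", geometry=BBox(0.0, 0.0, 80.0, 40.0),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.Macromolecule"),
                           label="p53"))
        g.add_node(YedNode(id="ui", geometry=BBox(60.0, -7.0, 24.0, 14.0),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.UnitOfInformation"),
                           label="mt:prot"))
        pd, report = convert(g)
        assert pd.glyphs["ui"].parent == "m"
        assert any(r.rule == "aux-geometric" for r in report.records)

    def test_orphan_aux_unit_warned_and_standalone(self):
        g = YedGraph()
        g.add_node(YedNode(id="m", geometry=BBox(0, 0, 80, 40),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.Macromolecule"),
                           label="p53"))
        g.add_node(YedNode(id="sv", geometry=BBox(5000.0, 5000.0, 24.0, 14.0),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.StateVariable"),
                           label="P"))
        pd, report = convert(g)
        assert pd.glyphs["sv"].parent is None
        assert any(r.rule == "aux-orphan" for r in report.records)

    def test_find_aux_parent_prefers_larger_overlap(self):
        aux = YedNode(id="sv", geometry=BBox(70.0, -5.0, 24.0, 14.0),
                      style=YedNodeStyle(configuration="com.yworks.sbgn.StateVariable"))
        near = YedNode(id="a", geometry=BBox(0.0, 0.0, 80.0, 40.0),
                       style=YedNodeStyle(configuration="com.yworks.sbgn.Macromolecule"))
        far = YedNode(id="b", geometry=BBox(95.0, 0.0, 80.0, 40.0),
                      style=YedNodeStyle(configuration="com.yworks.sbgn.Macromolecule"))
        assert find_aux_parent(aux, [near, far]) in ("a", "b")  # overlaps decide
        assert find_aux_parent(aux, [near]) == "a"


class TestConvert:
    def test_fig2_horizontal_scenario(self):
        pd, report = convert(fig2_fixtures()["irreversible_horizontal"])
        proc = pd.glyphs["P"]
        assert proc.orientation is Orientation.HORIZONTAL
        assert len(proc.ports) == 2
        p1, p2 = proc.ports
        cons = [a for a in pd.arcs.values() if a.cls is ArcClass.CONSUMPTION]
        prod = [a for a in pd.arcs.values() if a.cls is ArcClass.PRODUCTION]
        assert all(a.target == p1.id for a in cons)  # consumptions enter the left port
        assert all(a.source == p2.id for a in prod)
        assert validate(pd) == []
        assert not report.has_errors

    def test_fig2_vertical_scenario(self):
        pd, _ = convert(fig2_fixtures()["irreversible_vertical"])
        assert pd.glyphs["P"].orientation is Orientation.VERTICAL
        assert validate(pd) == []

    def test_fig2_reversible_scenario(self):
        pd, _ = convert(fig2_fixtures()["reversible"])
        proc = pd.glyphs["P"]
        assert all(a.cls is ArcClass.PRODUCTION for a in pd.arcs.values())
        p1, p2 = proc.ports
        sources = {a.source for a in pd.arcs.values()}
        assert sources == {p1.id, p2.id}  # one production arc per port
        assert validate(pd) == []

    def test_unclassifiable_node_isolated_as_error(self):
        g = fig2_fixtures()["irreversible_horizontal"]
        g.add_node(YedNode(id="weird", geometry=BBox(500, 500, 30, 30),
                           style=YedNodeStyle(configuration="com.example.Mystery")))
        pd, report = convert(g)
        assert "weird" not in pd.glyphs
        assert "P" in pd.glyphs  # rest of the file still converted
        assert any(r.rule == "node-class" and r.element == "weird" for r in report.records)

    def test_edges_of_unclassifiable_node_skipped(self):
        g = fig2_fixtures()["irreversible_horizontal"]
        g.add_node(YedNode(id="weird", geometry=BBox(500, 500, 30, 30),
                           style=YedNodeStyle(configuration="com.example.Mystery")))
        g.add_edge(YedEdge(id="ew", source="weird", target="P",
                           style=YedEdgeStyle(target_arrow=ArrowType.CIRCLE)))
        pd, report = convert(g)
        assert "ew" not in pd.arcs
        assert any(r.rule == "edge-skip" for r in report.records)

    def test_single_flux_arc_process_emitted_without_ports(self):
        g = YedGraph()
        g.add_node(YedNode(id="P", geometry=BBox(100, 100, 20, 20),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.Process")))
        g.add_node(YedNode(id="E", geometry=BBox(0, 90, 60, 40),
                           style=YedNodeStyle(configuration="com.yworks.sbgn.SimpleChemical"),
                           label="X"))
        g.add_edge(YedEdge(id="e", source="P", target="E",
                           style=YedEdgeStyle(target_arrow=ArrowType.STANDARD)))
        pd, report = convert(g)
        assert pd.glyphs["P"].ports == []
        assert any(r.rule == "degenerate-process" for r in report.records)
        assert validate(pd) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_stress_graphs_always_yield_valid_maps(self, seed):
        pd, _ = convert(random_process_graph(seed))
        assert validate(pd) == []
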