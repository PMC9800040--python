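import pytest

from ysbgn.pd_model import (
    Arc,
    ArcClass,
    BBox,
    Glyph,
    GlyphClass,
    Orientation,
    PDMap,
    Point,
    Port,
)
from ysbgn.report import ConversionReport
from ysbgn.sbgn_to_yed import convert, map_arc, map_glyph, render_ports
from ysbgn.yed_model import ArrowType, edge_class_of, node_class_of
from conftest import build_process_map


def _glyph(cls: GlyphClass, **kw) -> Glyph:
    return Glyph(id="g", cls=cls, bbox=BBox(0.0, 0.0, 80.0, 40.0), **kw)


class TestMapGlyph:
    @pytest.mark.parametrize(
        "cls,expected_config",
        [
            (GlyphClass.NUCLEIC_ACID_FEATURE, "com.yworks.sbgn.NucleicAcidFeature"),
            (GlyphClass.SIMPLE_CHEMICAL, "com.yworks.sbgn.SimpleChemical"),
            (GlyphClass.SOURCE_AND_SINK, "com.yworks.sbgn.EmptySet"),
            (GlyphClass.PHENOTYPE, "com.yworks.sbgn.Phenotype"),
            (GlyphClass.SUBMAP, "com.yworks.sbgn.Submap"),
        ],
    )
    def test_direct_configurations(self, cls, expected_config):
        assert map_glyph(_glyph(cls)).style.configuration == expected_config

    def test_geometry_copied_exactly(self):
        g = _glyph(GlyphClass.MACROMOLECULE)
        assert map_glyph(g).geometry == g.bbox

    def test_multimer_cardinality_becomes_mcount(self):
        node = map_glyph(_glyph(GlyphClass.MACROMOLECULE, multimer_cardinality=2))
        assert node.style.mcount == 2

    def test_omitted_and_uncertain_processes_use_marker_labels(self):
        assert map_glyph(_glyph(GlyphClass.OMITTED_PROCESS)).label == "\\\\"
        assert map_glyph(_glyph(GlyphClass.UNCERTAIN_PROCESS)).label == "?"

    def test_operator_stored_as_label(self):
        node = map_glyph(_glyph(GlyphClass.OR))
        assert node.style.configuration == "com.yworks.sbgn.Operator"
        assert node.label == "OR"

    def test_association_degrades_to_process_with_record(self):
        report = ConversionReport()
        node = map_glyph(_glyph(GlyphClass.ASSOCIATION), report)
        assert node.style.configuration == "com.yworks.sbgn.Process"
        assert [r.rule for r in report.degradations] == ["assoc_to_process"]

    def test_up_tag_degrades_to_left_tag(self):
        report = ConversionReport()
        node = map_glyph(_glyph(GlyphClass.TAG, orientation=Orientation.UP), report)
        assert node.style.configuration == "com.yworks.sbgn.Tag"
        assert not node.style.inverse
        assert [r.rule for r in report.degradations] == ["updown_tag_to_left"]

    def test_right_tag_sets_inverse_without_degradation(self):
        report = ConversionReport()
        node = map_glyph(_glyph(GlyphClass.TAG, orientation=Orientation.RIGHT), report)
        assert node.style.inverse
        assert report.degradations == []

    def test_clone_flag_carried_as_style_attr(self):
        node = map_glyph(_glyph(GlyphClass.SIMPLE_CHEMICAL, clone=True))
        assert node.style.clone

    def test_aux_unit_is_a_contract_error(self):
        with pytest.raises(ValueError):
            map_glyph(_glyph(GlyphClass.STATE_VARIABLE, state=("P", None)))

    def test_class_preservation_through_classification(self):
        """Forward map then classify returns the original class for direct classes."""
        direct = [
            c for c in GlyphClass
            if c not in (
                GlyphClass.ASSOCIATION, GlyphClass.DISSOCIATION,
                GlyphClass.STATE_VARIABLE, GlyphClass.UNIT_OF_INFORMATION,
            )
        ]
        for cls in direct:
            node = map_glyph(_glyph(cls))
            assert node_class_of(node.style, node.label) is cls, cls


class TestMapArc:
    @pytest.mark.parametrize(
        "cls,arrow",
        [
            (ArcClass.NECESSARY_STIMULATION, ArrowType.WHITE_DELTA_BAR),
            (ArcClass.MODULATION, ArrowType.WHITE_DIAMOND),
            (ArcClass.CATALYSIS, ArrowType.CIRCLE),
        ],
    )
    def test_arrow_styles(self, process_map, cls, arrow):
        arc = Arc(id="x", cls=cls, source="C0", target="P")
        assert map_arc(arc, process_map).style.target_arrow is arrow

    def test_port_endpoint_collapses_to_process_node(self, process_map):
        edge = map_arc(process_map.arcs["ap0"], process_map)
        assert edge.source == "P"  # was port P.2
        assert edge.target == "R0"

    def test_arc_class_preserved_for_all_seven_classes(self, process_map):
        for cls in ArcClass:
            edge = map_arc(Arc(id="x", cls=cls, source="C0", target="P"), process_map)
            assert edge_class_of(edge.style) is cls


class TestRenderPorts:
    def test_consumption_edge_gains_last_bend_at_port(self):
        pd = build_process_map(n_consumption=1, n_production=1)
        graph, _ = convert(pd)
        # consumption entity -> process: port P.1 at (90, 110) is on the target side
        assert graph.edges["ac0"].bends[-1] == Point(90.0, 110.0)
        # production process -> entity: port P.2 at (130, 110) on the source side
        assert graph.edges["ap0"].bends[0] == Point(130.0, 110.0)

    def test_existing_bends_preserved_in_order(self, process_map):
        process_map.arcs["ac0"].bends = [Point(50.0, 80.0)]
        graph, _ = convert(process_map)
        assert graph.edges["ac0"].bends == [Point(50.0, 80.0), Point(90.0, 110.0)]

    def test_process_without_incident_arcs_has_no_edits(self):
        pd = PDMap()
        proc = Glyph(id="P", cls=GlyphClass.PROCESS, bbox=BBox(0, 0, 20, 20))
        proc.ports = [
            Port(id="P.1", position=Point(-10.0, 10.0), owner="P"),
            Port(id="P.2", position=Point(30.0, 10.0), owner="P"),
        ]
        pd.add_glyph(proc)
        render_ports(proc, [], {})  # no incident arcs: nothing to do, no error


class TestConvert:
    def test_counts_on_mixed_fixture(self):
        pd = PDMap()
        pd.add_glyph(Glyph(id="comp", cls=GlyphClass.COMPARTMENT, bbox=BBox(0, 0, 500, 400)))
        pd.add_glyph(Glyph(id="m", cls=GlyphClass.MACROMOLECULE, bbox=BBox(20, 50, 80, 40),
                           label="E1", compartment_ref="comp", children=["sv"]))
        pd.add_glyph(Glyph(id="sv", cls=GlyphClass.STATE_VARIABLE, bbox=BBox(30, 43, 24, 14),
                           parent="m", state=("P", None)))
        pd.add_glyph(Glyph(id="s", cls=GlyphClass.SIMPLE_CHEMICAL, bbox=BBox(200, 50, 60, 40),
                           label="atp", compartment_ref="comp"))
        pd.add_glyph(Glyph(id="P", cls=GlyphClass.PROCESS, bbox=BBox(130, 60, 20, 20),
                           compartment_ref="comp"))
        pd.add_arc(Arc(id="a1", cls=ArcClass.CONSUMPTION, source="m", target="P"))
        pd.add_arc(Arc(id="a2", cls=ArcClass.PRODUCTION, source="P", target="s"))
        graph, report = convert(pd)
        assert len(graph.nodes) == 5
        assert sum(1 for n in graph.nodes.values() if n.style.is_group) == 1
        assert len(graph.edges) == 2
        assert graph.nodes["m"].aux_refs == ["sv"]
        assert graph.nodes["m"].parent_group == "comp"
        assert not report.has_errors

    def test_single_association_yields_exactly_one_degradation(self):
        pd = PDMap()
        pd.add_glyph(_glyph(GlyphClass.ASSOCIATION))
        _, report = convert(pd)
        assert len(report.degradations) == 1

    def test_empty_map(self):
        graph, report = convert(PDMap())
        assert not graph.nodes and not graph.edges and not report.records

    def test_node_and_edge_cardinality_matches_map(self):
        pd = build_process_map()
        graph, _ = convert(pd)
        assert len(graph.nodes) == len(pd.glyphs)
        assert len(graph.edges) == len(pd.arcs)
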