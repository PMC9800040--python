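"""Forward converter: SBGN PD map → yEd GraphML graph.

Most glyph classes map one-to-one onto the yEd SBGN palette.  The exceptions
are handled here and logged as degradations: association/dissociation become
generic processes, up/down tags become left tags.  Process ports have no yEd
counterpart, so every flux arc gains a bend point at its port position — all
edges of one port then visually converge on the antenna tip while connecting
to the process box itself.  Conversion never aborts on a single bad element;
failures are collected in the report.
"""

from __future__ import annotations

from typing import Optional

from .pd_model import (
    AUX_CLASSES,
    Arc,
    FLUX_ARC_CLASSES,
    Glyph,
    GlyphClass,
    LOGIC_CLASSES,
    Orientation,
    PDMap,
    PROCESS_CLASSES,
    validate,
)
from .report import ConversionReport, DegradationRule
from .yed_model import (
    ARC_TO_ARROWS,
    ATTR_CLONE,
    ATTR_CLONE_LABEL,
    ATTR_INVERSE,
    ATTR_MCOUNT,
    CONFIG_COMPLEX,
    CONFIG_EMPTY_SET,
    CONFIG_GROUP,
    CONFIG_MACROMOLECULE,
    CONFIG_NUCLEIC_ACID_FEATURE,
    CONFIG_OPERATOR,
    CONFIG_PERTURBING_AGENT,
    CONFIG_PHENOTYPE,
    CONFIG_PROCESS,
    CONFIG_SIMPLE_CHEMICAL,
    CONFIG_STATE_VARIABLE,
    CONFIG_SUBMAP,
    CONFIG_TAG,
    CONFIG_UNIT_OF_INFORMATION,
    CONFIG_UNSPECIFIED_ENTITY,
    LABEL_OMITTED,
    LABEL_UNCERTAIN,
    YedEdge,
    YedEdgeStyle,
    YedGraph,
    YedNode,
    YedNodeStyle,
)
from .graphml_io import EXT_ATTR_PREFIX

_DIRECT_CONFIGS: dict[GlyphClass, str] = {
    GlyphClass.COMPLEX: CONFIG_COMPLEX,
    GlyphClass.MACROMOLECULE: CONFIG_MACROMOLECULE,
    GlyphClass.NUCLEIC_ACID_FEATURE: CONFIG_NUCLEIC_ACID_FEATURE,
    GlyphClass.SIMPLE_CHEMICAL: CONFIG_SIMPLE_CHEMICAL,
    GlyphClass.UNSPECIFIED_ENTITY: CONFIG_UNSPECIFIED_ENTITY,
    GlyphClass.PERTURBING_AGENT: CONFIG_PERTURBING_AGENT,
    GlyphClass.PHENOTYPE: CONFIG_PHENOTYPE,
    GlyphClass.SOURCE_AND_SINK: CONFIG_EMPTY_SET,
    GlyphClass.SUBMAP: CONFIG_SUBMAP,
}


def map_glyph(g: Glyph, report: Optional[ConversionReport] = None) -> YedNode:
    """Map one non-auxiliary glyph to its yEd node (Table-style encoding).

    Degradations (association/dissociation → process, up/down tag → left tag)
    are appended to *report*.  Passing a state variable or unit of information
    is a contract error — auxiliary units are emitted by the attach pass.
    """
    if g.cls in AUX_CLASSES:
        raise ValueError(f"auxiliary-unit glyph {g.id!r} must not be passed to map_glyph")
    report = report if report is not None else ConversionReport()
    style = YedNodeStyle(configuration=CONFIG_PROCESS)
    label = g.label

    if g.cls is GlyphClass.COMPARTMENT:
        style.configuration = CONFIG_GROUP
        style.is_group = True
    elif g.cls is GlyphClass.COMPLEX:
        style.configuration = CONFIG_COMPLEX
        style.is_group = True
    elif g.cls in _DIRECT_CONFIGS:
        style.configuration = _DIRECT_CONFIGS[g.cls]
    elif g.cls is GlyphClass.PROCESS:
        style.configuration = CONFIG_PROCESS
    elif g.cls is GlyphClass.OMITTED_PROCESS:
        style.configuration = CONFIG_PROCESS
        label = LABEL_OMITTED
    elif g.cls is GlyphClass.UNCERTAIN_PROCESS:
        style.configuration = CONFIG_PROCESS
        label = LABEL_UNCERTAIN
    elif g.cls is GlyphClass.ASSOCIATION:
        style.configuration = CONFIG_PROCESS
        report.degradation(
            DegradationRule.ASSOC_TO_PROCESS, g.id,
            "association has no yEd palette shape; shown as a generic process",
        )
    elif g.cls is GlyphClass.DISSOCIATION:
        style.configuration = CONFIG_PROCESS
        report.degradation(
            DegradationRule.DISSOC_TO_PROCESS, g.id,
            "dissociation has no yEd palette shape; shown as a generic process",
        )
    elif g.cls in LOGIC_CLASSES:
        style.configuration = CONFIG_OPERATOR
        label = g.cls.value.upper()
    elif g.cls is GlyphClass.TAG:
        style.configuration = CONFIG_TAG
        if g.orientation is Orientation.RIGHT:
            style.style_attrs[ATTR_INVERSE] = "true"
        elif g.orientation in (Orientation.UP, Orientation.DOWN):
            report.degradation(
                DegradationRule.UPDOWN_TAG_TO_LEFT, g.id,
                f"{g.orientation.value}-oriented tag has no yEd shape; emitted left-oriented",
            )
    else:  # pragma: no cover - enumeration is closed
        raise ValueError(f"unmapped glyph class {g.cls!r}")

    if g.multimer_cardinality is not None:
        style.style_attrs[ATTR_MCOUNT] = str(g.multimer_cardinality)
    if g.clone:
        style.style_attrs[ATTR_CLONE] = "true"
        if g.clone_label is not None:
            style.style_attrs[ATTR_CLONE_LABEL] = g.clone_label
    _carry_extension(g.extension, style)

    return YedNode(id=g.id, geometry=g.bbox, style=style, label=label)


def _carry_extension(extension: dict[str, str], style: YedNodeStyle) -> None:
    for key, value in extension.items():
        if key in ("fill", "stroke"):
            style.style_attrs[key] = value
        else:
            style.style_attrs[EXT_ATTR_PREFIX + key] = value


def _map_aux_glyph(g: Glyph) -> YedNode:
    """Auxiliary units become satellite nodes referenced from their parent."""
    if g.cls is GlyphClass.STATE_VARIABLE:
        config = CONFIG_STATE_VARIABLE
        value, variable = g.state if g.state is not None else (None, None)
        if variable:
            label = f"{value or ''}@{variable}"
        else:
            label = value or None
    else:
        config = CONFIG_UNIT_OF_INFORMATION
        label = g.label
    style = YedNodeStyle(configuration=config)
    _carry_extension(g.extension, style)
    return YedNode(id=g.id, geometry=g.bbox, style=style, label=label)


def map_arc(
    a: Arc,
    pd: PDMap,
    report: Optional[ConversionReport] = None,
    port_owner: Optional[dict[str, str]] = None,
) -> YedEdge:
    """Map an arc to a polyline edge; port endpoints collapse to the owner node."""
    if port_owner is None:
        port_owner = {p.id: p.owner for p in pd.iter_ports()}

    def collapse(ref: str) -> str:
        return port_owner.get(ref, ref)

    src_arrow, tgt_arrow = ARC_TO_ARROWS[a.cls]
    edge = YedEdge(
        id=a.id,
        source=collapse(a.source),
        target=collapse(a.target),
        style=YedEdgeStyle(source_arrow=src_arrow, target_arrow=tgt_arrow,
                           colour=a.extension.get("stroke")),
        bends=list(a.bends),
    )
    return edge


def render_ports(process: Glyph, incident: list[Arc], edges: dict[str, YedEdge]) -> None:
    """Add a bend at each port position to every flux edge attached to it.

    The bend is prepended when the port sits on the edge's source side and
    appended otherwise, so all edges of one port converge on the antenna tip
    while their endpoints stay on the process box.
    """
    port_pos = {p.id: p.position for p in process.ports}
    for arc in incident:
        edge = edges.get(arc.id)
        if edge is None:
            continue
        if arc.source in port_pos:
            edge.bends.insert(0, port_pos[arc.source])
        elif arc.target in port_pos:
            edge.bends.append(port_pos[arc.target])


def convert(pd: PDMap, strict: bool = False) -> tuple[YedGraph, ConversionReport]:
    """Convert a whole PD map to a yEd graph.

    One node per glyph (compartments and complexes as groups, auxiliary units
    as satellite nodes with ``aux_refs`` on the parent), one edge per arc.
    Per-element failures are reported, never raised, unless ``strict``.
    """
    report = ConversionReport()
    for v in validate(pd):
        if strict:
            raise ValueError(f"invalid PD map: {v.rule} on {v.element}: {v.message}")
        report.warn(v.rule, v.element, v.message)

    graph = YedGraph()
    skipped: set[str] = set()

    for g in pd.glyphs.values():
        try:
            node = _map_aux_glyph(g) if g.cls in AUX_CLASSES else map_glyph(g, report)
        except Exception as exc:  # noqa: BLE001 - error isolation is the contract
            report.error("glyph-map", g.id, str(exc))
            skipped.add(g.id)
            continue
        graph.add_node(node)

    # containment and aux references once all nodes exist
    for g in pd.glyphs.values():
        node = graph.nodes.get(g.id)
        if node is None:
            continue
        parent = pd.glyphs.get(g.parent) if g.parent else None
        if parent is not None and parent.id in graph.nodes:
            if g.cls in AUX_CLASSES:
                graph.nodes[parent.id].aux_refs.append(g.id)
                node.parent_group = graph.nodes[parent.id].parent_group
            else:
                node.parent_group = parent.id
        elif g.compartment_ref and g.compartment_ref in graph.nodes:
            node.parent_group = g.compartment_ref

    port_owner = {p.id: g.id for g in pd.glyphs.values() for p in g.ports}
    for a in pd.arcs.values():
        src_glyph = port_owner.get(a.source, a.source)
        tgt_glyph = port_owner.get(a.target, a.target)
        if src_glyph in skipped or tgt_glyph in skipped:
            report.error("arc-skip", a.id, "endpoint glyph failed to convert")
            continue
        if src_glyph not in graph.nodes or tgt_glyph not in graph.nodes:
            report.error("arc-skip", a.id, "endpoint does not resolve")
            continue
        graph.add_edge(map_arc(a, pd, report, port_owner=port_owner))

    arcs_by_owner: dict[str, list[Arc]] = {}
    for a in pd.arcs.values():
        if a.cls in FLUX_ARC_CLASSES:
            for ref in (a.source, a.target):
                owner = port_owner.get(ref)
                if owner is not None:
                    arcs_by_owner.setdefault(owner, []).append(a)
    for g in pd.glyphs.values():
        if g.cls in PROCESS_CLASSES and g.ports:
            render_ports(g, arcs_by_owner.get(g.id, []), graph.edges)

    return graph, report
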