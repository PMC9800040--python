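"""Read and write yEd-flavoured GraphML.

The dialect is frozen here: GraphML core namespace, the yFiles extension
namespace, the ``<key>`` declarations, Table-style generic-node configuration
strings and the arrowhead tokens.  Compartments and complexes are emitted as
yEd *group* nodes, i.e. nested ``<graph>`` elements; auxiliary-unit references
travel in a converter-owned ``ysbgn.auxrefs`` data key (space-separated node
ids).  Exact arrow token spellings are yEd-version-dependent; this module is
the single place to adjust them.
"""

from __future__ import annotations

import io
from typing import IO, Optional, Union

from lxml import etree

from .pd_model import BBox, Point
from .yed_model import (
    ArrowType,
    CONFIG_GROUP,
    YedEdge,
    YedEdgeStyle,
    YedGraph,
    YedNode,
    YedNodeStyle,
)

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
Y_NS = "http://www.yworks.com/xml/graphml"

KEY_NODE_GRAPHICS = "d0"
KEY_EDGE_GRAPHICS = "d1"
KEY_AUX_REFS = "d2"
KEY_NODE_DESCRIPTION = "d3"
KEY_EDGE_DESCRIPTION = "d4"

#: style_attrs prefix under which PD extension entries ride through GraphML
EXT_ATTR_PREFIX = "ysbgn.ext."

PathOrStream = Union[str, "io.IOBase", IO[bytes]]


class GraphmlParseError(ValueError):
    pass


class GraphIntegrityError(ValueError):
    """An edge or aux reference that does not resolve to a node."""


def _g(tag: str) -> str:
    return f"{{{GRAPHML_NS}}}{tag}"


def _y(tag: str) -> str:
    return f"{{{Y_NS}}}{tag}"


def _num(value: float) -> str:
    return repr(float(value))


# ---------------------------------------------------------------------------
# reading


def read_graphml(source: PathOrStream) -> YedGraph:
    """Parse yEd GraphML into a :class:`~ysbgn.yed_model.YedGraph`.

    Nested ``<graph>`` elements become group nodes with ``parent_group``
    links on their members; unknown node realizers are kept with a
    pseudo-configuration (``y:<LocalName>``) so classification errors can be
    reported per element later instead of failing the parse.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise GraphmlParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root.tag).localname != "graphml":
        raise GraphmlParseError(f"not a GraphML document (root {root.tag!r})")

    graph = YedGraph()
    top = root.find(_g("graph"))
    if top is None:
        raise GraphmlParseError("missing top-level <graph> element")

    def walk(graph_el, parent_group: Optional[str]) -> None:
        for node_el in graph_el.findall(_g("node")):
            node = _parse_node(node_el, parent_group)
            graph.add_node(node)
            sub = node_el.find(_g("graph"))
            if sub is not None:
                node.style.is_group = True
                walk(sub, node.id)
        for edge_el in graph_el.findall(_g("edge")):
            graph.add_edge(_parse_edge(edge_el))

    walk(top, None)

    for edge in graph.edges.values():
        for ref in (edge.source, edge.target):
            if ref not in graph.nodes:
                raise GraphIntegrityError(f"edge {edge.id!r} references unknown node {ref!r}")
    return graph


def _parse_node(node_el, parent_group: Optional[str]) -> YedNode:
    nid = node_el.get("id")
    style = YedNodeStyle(configuration="y:Unknown")
    geometry = BBox(0.0, 0.0, 1.0, 1.0)
    label: Optional[str] = None
    aux_refs: list[str] = []

    for data_el in node_el.findall(_g("data")):
        key = data_el.get("key")
        if key == KEY_AUX_REFS:
            aux_refs = (data_el.text or "").split()
            continue
        realizer = next(iter(data_el), None)
        if realizer is None or etree.QName(realizer.tag).namespace != Y_NS:
            continue
        local = etree.QName(realizer.tag).localname
        if local == "GroupNode":
            style.configuration = CONFIG_GROUP
            style.is_group = True
        elif local in ("GenericNode", "GenericGroupNode"):
            style.configuration = realizer.get("configuration", "y:Unknown")
            style.is_group = local == "GenericGroupNode"
        else:
            style.configuration = f"y:{local}"
        geom_el = realizer.find(_y("Geometry"))
        if geom_el is not None:
            geometry = BBox(
                float(geom_el.get("x")),
                float(geom_el.get("y")),
                float(geom_el.get("width")),
                float(geom_el.get("height")),
            )
        fill_el = realizer.find(_y("Fill"))
        if fill_el is not None and fill_el.get("color"):
            style.style_attrs["fill"] = fill_el.get("color")
        border_el = realizer.find(_y("BorderStyle"))
        if border_el is not None and border_el.get("color"):
            style.style_attrs["stroke"] = border_el.get("color")
        label_el = realizer.find(_y("NodeLabel"))
        if label_el is not None and label_el.text is not None:
            label = label_el.text
        props_el = realizer.find(_y("StyleProperties"))
        if props_el is not None:
            for prop_el in props_el.findall(_y("Property")):
                name = prop_el.get("name")
                if name:
                    style.style_attrs[name] = prop_el.get("value", "")

    return YedNode(
        id=nid,
        geometry=geometry,
        style=style,
        label=label,
        parent_group=parent_group,
        aux_refs=aux_refs,
    )


def _parse_edge(edge_el) -> YedEdge:
    eid = edge_el.get("id")
    edge = YedEdge(id=eid, source=edge_el.get("source"), target=edge_el.get("target"))
    for data_el in edge_el.findall(_g("data")):
        realizer = next(iter(data_el), None)
        if realizer is None or etree.QName(realizer.tag).namespace != Y_NS:
            continue
        path_el = realizer.find(_y("Path"))
        if path_el is not None:
            for point_el in path_el.findall(_y("Point")):
                edge.bends.append(Point(float(point_el.get("x")), float(point_el.get("y"))))
        line_el = realizer.find(_y("LineStyle"))
        if line_el is not None and line_el.get("color"):
            edge.style.colour = line_el.get("color")
        arrows_el = realizer.find(_y("Arrows"))
        if arrows_el is not None:
            edge.style.source_arrow = _arrow(arrows_el.get("source", "none"), eid)
            edge.style.target_arrow = _arrow(arrows_el.get("target", "none"), eid)
        label_el = realizer.find(_y("EdgeLabel"))
        if label_el is not None and label_el.text is not None:
            edge.label = label_el.text
    return edge


def _arrow(token: str, edge_id: str) -> ArrowType:
    try:
        return ArrowType(token)
    except ValueError:
        raise GraphmlParseError(f"edge {edge_id!r}: unknown arrow token {token!r}") from None


# ---------------------------------------------------------------------------
# writing


def write_graphml(graph: YedGraph, dest: PathOrStream) -> None:
    """Serialize a :class:`YedGraph`; ``read_graphml`` inverts this exactly."""
    for edge in graph.edges.values():
        for ref in (edge.source, edge.target):
            if ref not in graph.nodes:
                raise GraphIntegrityError(f"edge {edge.id!r} references unknown node {ref!r}")
    for node in graph.nodes.values():
        for ref in node.aux_refs:
            if ref not in graph.nodes:
                raise GraphIntegrityError(f"node {node.id!r} aux ref {ref!r} does not resolve")

    nsmap = {None: GRAPHML_NS, "y": Y_NS}
    root = etree.Element(_g("graphml"), nsmap=nsmap)
    for key_id, target, yfiles_type, attr_name in (
        (KEY_NODE_GRAPHICS, "node", "nodegraphics", None),
        (KEY_EDGE_GRAPHICS, "edge", "edgegraphics", None),
        (KEY_AUX_REFS, "node", None, "ysbgn.auxrefs"),
        (KEY_NODE_DESCRIPTION, "node", None, "description"),
        (KEY_EDGE_DESCRIPTION, "edge", None, "description"),
    ):
        key_el = etree.SubElement(root, _g("key"))
        key_el.set("id", key_id)
        key_el.set("for", target)
        if yfiles_type is not None:
            key_el.set("yfiles.type", yfiles_type)
        if attr_name is not None:
            key_el.set("attr.name", attr_name)
            key_el.set("attr.type", "string")

    top = etree.SubElement(root, _g("graph"))
    top.set("id", "G")
    top.set("edgedefault", "directed")

    members: dict[str, list[YedNode]] = {}
    for node in graph.nodes.values():
        if node.parent_group is not None:
            members.setdefault(node.parent_group, []).append(node)

    def emit_node(node: YedNode, container) -> None:
        node_el = etree.SubElement(container, _g("node"))
        node_el.set("id", node.id)
        if node.style.is_group:
            node_el.set("yfiles.foldertype", "group")
        data_el = etree.SubElement(node_el, _g("data"))
        data_el.set("key", KEY_NODE_GRAPHICS)
        if node.style.is_group and node.style.configuration == CONFIG_GROUP:
            realizer = etree.SubElement(data_el, _y("GroupNode"))
        elif node.style.is_group:
            realizer = etree.SubElement(data_el, _y("GenericGroupNode"))
            realizer.set("configuration", node.style.configuration)
        else:
            realizer = etree.SubElement(data_el, _y("GenericNode"))
            realizer.set("configuration", node.style.configuration)
        geom_el = etree.SubElement(realizer, _y("Geometry"))
        geom_el.set("x", _num(node.geometry.x))
        geom_el.set("y", _num(node.geometry.y))
        geom_el.set("width", _num(node.geometry.w))
        geom_el.set("height", _num(node.geometry.h))
        fill = node.style.style_attrs.get("fill")
        if fill:
            etree.SubElement(realizer, _y("Fill")).set("color", fill)
        stroke = node.style.style_attrs.get("stroke")
        if stroke:
            etree.SubElement(realizer, _y("BorderStyle")).set("color", stroke)
        if node.label is not None:
            etree.SubElement(realizer, _y("NodeLabel")).text = node.label
        props = {
            k: v
            for k, v in node.style.style_attrs.items()
            if k not in ("fill", "stroke")
        }
        if props:
            props_el = etree.SubElement(realizer, _y("StyleProperties"))
            for name in sorted(props):
                prop_el = etree.SubElement(props_el, _y("Property"))
                prop_el.set("name", name)
                prop_el.set("value", props[name])
        if node.aux_refs:
            aux_el = etree.SubElement(node_el, _g("data"))
            aux_el.set("key", KEY_AUX_REFS)
            aux_el.text = " ".join(node.aux_refs)
        if node.style.is_group:
            sub_el = etree.SubElement(node_el, _g("graph"))
            sub_el.set("id", f"{node.id}:")
            sub_el.set("edgedefault", "directed")
            for child in sorted(members.get(node.id, []), key=lambda n: n.id):
                emit_node(child, sub_el)

    for node in graph.nodes.values():
        if node.parent_group is None:
            emit_node(node, top)

    for edge in graph.edges.values():
        edge_el = etree.SubElement(top, _g("edge"))
        edge_el.set("id", edge.id)
        edge_el.set("source", edge.source)
        edge_el.set("target", edge.target)
        data_el = etree.SubElement(edge_el, _g("data"))
        data_el.set("key", KEY_EDGE_GRAPHICS)
        poly_el = etree.SubElement(data_el, _y("PolyLineEdge"))
        path_el = etree.SubElement(poly_el, _y("Path"))
        for attr in ("sx", "sy", "tx", "ty"):
            path_el.set(attr, "0.0")
        for bend in edge.bends:
            point_el = etree.SubElement(path_el, _y("Point"))
            point_el.set("x", _num(bend.x))
            point_el.set("y", _num(bend.y))
        line_el = etree.SubElement(poly_el, _y("LineStyle"))
        line_el.set("type", "line")
        line_el.set("width", "1.0")
        if edge.style.colour:
            line_el.set("color", edge.style.colour)
        arrows_el = etree.SubElement(poly_el, _y("Arrows"))
        arrows_el.set("source", edge.style.source_arrow.value)
        arrows_el.set("target", edge.style.target_arrow.value)
        if edge.label is not None:
            etree.SubElement(poly_el, _y("EdgeLabel")).text = edge.label

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if isinstance(dest, str):
        with open(dest, "wb") as fh:
            fh.write(data)
    else:
        dest.write(data)


def graphml_bytes(graph: YedGraph) -> bytes:
    buf = io.BytesIO()
    write_graphml(graph, buf)
    return buf.getvalue()
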