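"""Read and write SBGN-ML (Process Description, milestone 2).

The writer always emits the milestone-2 namespace; the reader additionally
tolerates milestone-3 era namespaces (``http://sbgn.org/libsbgn/0.3`` and
friends) so files from newer tooling still load.  Colours and annotations
travel in a converter-owned ``<extension>`` payload; unknown extension
children are preserved verbatim as opaque strings, so third-party metadata
survives a round trip untouched.
"""

from __future__ import annotations

import io
import re
from typing import IO, Optional, Union

from lxml import etree

from .pd_model import (
    Arc,
    ArcClass,
    BBox,
    Glyph,
    GlyphClass,
    Orientation,
    PDMap,
    Point,
    Port,
    validate,
)
from .report import ConversionReport
from .schema import SBGN_M2_NS

#: Converter-owned namespace for the colour/annotation extension payload.
YSBGN_EXT_NS = "urn:ysbgn:dialect"

_SBGN_NS_RE = re.compile(r"^http://sbgn\.org/libsbgn/\d+(\.\d+)*$")

#: Multimer variants are serialized as "<base> multimer" class strings.
_MULTIMER_SUFFIX = " multimer"

PathOrStream = Union[str, "io.IOBase", IO[bytes]]


class SbgnParseError(ValueError):
    """Malformed XML or structurally invalid SBGN-ML content."""


class UnsupportedLanguageError(SbgnParseError):
    """The map is not written in the process description language."""


class ReferenceResolutionError(SbgnParseError):
    """An id reference (arc endpoint, compartmentRef) does not resolve."""

    def __init__(self, ids: list[str]):
        self.ids = ids
        super().__init__("dangling references: " + ", ".join(sorted(ids)))


class MapValidationError(ValueError):
    """Refusal to write a map that fails PD validation in strict mode."""


def _num(value: float) -> str:
    # repr round-trips floats exactly; trim a trailing ".0" only never — keep it
    return repr(float(value))


def _qn(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


# ---------------------------------------------------------------------------
# reading


def read_sbgnml(source: PathOrStream, report: Optional[ConversionReport] = None) -> PDMap:
    """Parse an SBGN-ML PD file into a :class:`~ysbgn.pd_model.PDMap`.

    Flux-arc directionality (consumption entity→port, production port→entity)
    is normalized on the way in; a flipped arc produces a warning in *report*
    rather than a failure.
    """
    report = report if report is not None else ConversionReport()
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise SbgnParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    ns = etree.QName(root.tag).namespace or ""
    if _local(root.tag) != "sbgn" or not _SBGN_NS_RE.match(ns):
        raise SbgnParseError(f"not an SBGN-ML document (root {root.tag!r})")
    map_el = root.find(_qn(ns, "map"))
    if map_el is None:
        raise SbgnParseError("missing <map> element")
    language = map_el.get("language", "")
    if language != "process description":
        raise UnsupportedLanguageError(f"unsupported map language {language!r}")

    pd = PDMap()

    def parse_glyph(el, parent: Optional[Glyph]) -> Glyph:
        gid = el.get("id")
        raw_cls = el.get("class", "")
        multimer = None
        if raw_cls.endswith(_MULTIMER_SUFFIX):
            raw_cls = raw_cls[: -len(_MULTIMER_SUFFIX)]
            multimer = 2  # refined from the extension payload below, if present
        try:
            cls = GlyphClass(raw_cls)
        except ValueError:
            raise SbgnParseError(f"unknown glyph class {el.get('class')!r} on {gid!r}") from None
        bbox_el = el.find(_qn(ns, "bbox"))
        if bbox_el is None:
            raise SbgnParseError(f"glyph {gid!r} has no bbox")
        g = Glyph(
            id=gid,
            cls=cls,
            bbox=BBox(
                float(bbox_el.get("x")),
                float(bbox_el.get("y")),
                float(bbox_el.get("w")),
                float(bbox_el.get("h")),
            ),
            compartment_ref=el.get("compartmentRef"),
            parent=parent.id if parent is not None else None,
            multimer_cardinality=multimer,
        )
        ori = el.get("orientation")
        if ori is not None:
            g.orientation = Orientation(ori)
        label_el = el.find(_qn(ns, "label"))
        if label_el is not None:
            g.label = label_el.get("text")
        state_el = el.find(_qn(ns, "state"))
        if state_el is not None:
            g.state = (state_el.get("value"), state_el.get("variable"))
        clone_el = el.find(_qn(ns, "clone"))
        if clone_el is not None:
            g.clone = True
            cl = clone_el.find(_qn(ns, "label"))
            if cl is not None:
                g.clone_label = cl.get("text")
        ext_el = el.find(_qn(ns, "extension"))
        if ext_el is not None:
            card = _read_extension(ext_el, g.extension)
            if card is not None:
                g.multimer_cardinality = card
        for port_el in el.findall(_qn(ns, "port")):
            g.ports.append(
                Port(
                    id=port_el.get("id"),
                    position=Point(float(port_el.get("x")), float(port_el.get("y"))),
                    owner=gid,
                )
            )
        pd.add_glyph(g)
        for child_el in el.findall(_qn(ns, "glyph")):
            child = parse_glyph(child_el, g)
            g.children.append(child.id)
        return g

    for glyph_el in map_el.findall(_qn(ns, "glyph")):
        parse_glyph(glyph_el, None)

    ports = pd.port_index()
    for arc_el in map_el.findall(_qn(ns, "arc")):
        aid = arc_el.get("id")
        try:
            cls = ArcClass(arc_el.get("class", ""))
        except ValueError:
            raise SbgnParseError(f"unknown arc class {arc_el.get('class')!r} on {aid!r}") from None
        arc = Arc(id=aid, cls=cls, source=arc_el.get("source"), target=arc_el.get("target"))
        for next_el in arc_el.findall(_qn(ns, "next")):
            arc.bends.append(Point(float(next_el.get("x")), float(next_el.get("y"))))
        ext_el = arc_el.find(_qn(ns, "extension"))
        if ext_el is not None:
            _read_extension(ext_el, arc.extension)
        # normalize flux-arc direction: consumption entity->port, production port->entity
        if cls is ArcClass.CONSUMPTION and arc.source in ports and arc.target not in ports:
            arc.source, arc.target = arc.target, arc.source
            arc.bends.reverse()
            report.warn("arc-direction", aid, "consumption arc left a port; direction normalized")
        elif cls is ArcClass.PRODUCTION and arc.target in ports and arc.source not in ports:
            arc.source, arc.target = arc.target, arc.source
            arc.bends.reverse()
            report.warn("arc-direction", aid, "production arc entered a port; direction normalized")
        pd.add_arc(arc)

    dangling = []
    known = set(pd.glyphs) | set(ports)
    for g in pd.glyphs.values():
        if g.compartment_ref is not None and g.compartment_ref not in pd.glyphs:
            dangling.append(g.compartment_ref)
    for a in pd.arcs.values():
        for ref in (a.source, a.target):
            if ref not in known:
                dangling.append(ref)
    if dangling:
        raise ReferenceResolutionError(dangling)
    return pd


def _read_extension(ext_el, into: dict[str, str]) -> Optional[int]:
    """Fill *into* from an <extension> element; returns multimer cardinality if present."""
    card = None
    raw_idx = 0
    for child in ext_el:
        if isinstance(child.tag, str) and etree.QName(child.tag).namespace == YSBGN_EXT_NS:
            for key, value in child.attrib.items():
                if key == "multimerCardinality":
                    card = int(value)
                else:
                    into[key] = value
        else:
            into[f"raw{raw_idx}"] = etree.tostring(child, encoding="unicode")
            raw_idx += 1
    return card


# ---------------------------------------------------------------------------
# writing


def write_sbgnml(
    pd: PDMap,
    dest: PathOrStream,
    strict: bool = True,
    report: Optional[ConversionReport] = None,
) -> None:
    """Serialize a map as milestone-2 SBGN-ML (glyphs before arcs).

    In strict mode (default) a map with PD violations is refused with
    :class:`MapValidationError`; with ``strict=False`` the violations are
    logged to *report* and the file written anyway.
    """
    report = report if report is not None else ConversionReport()
    violations = validate(pd)
    if violations:
        if strict:
            raise MapValidationError(
                f"{len(violations)} PD violation(s); first: {violations[0].rule} on "
                f"{violations[0].element}: {violations[0].message}"
            )
        for v in violations:
            report.warn(v.rule, v.element, f"writing anyway: {v.message}")

    nsmap = {None: SBGN_M2_NS}
    root = etree.Element(_qn(SBGN_M2_NS, "sbgn"), nsmap=nsmap)
    map_el = etree.SubElement(root, _qn(SBGN_M2_NS, "map"))
    map_el.set("language", pd.language)

    def emit_glyph(g: Glyph, container) -> None:
        el = etree.SubElement(container, _qn(SBGN_M2_NS, "glyph"))
        el.set("id", g.id)
        cls_str = g.cls.value
        if g.multimer_cardinality is not None:
            cls_str += _MULTIMER_SUFFIX
        el.set("class", cls_str)
        if g.compartment_ref is not None:
            el.set("compartmentRef", g.compartment_ref)
        if g.orientation is not None:
            el.set("orientation", g.orientation.value)
        _emit_extension(el, g.extension, g.multimer_cardinality)
        if g.label is not None:
            etree.SubElement(el, _qn(SBGN_M2_NS, "label")).set("text", g.label)
        if g.state is not None:
            state_el = etree.SubElement(el, _qn(SBGN_M2_NS, "state"))
            if g.state[0] is not None:
                state_el.set("value", g.state[0])
            if g.state[1] is not None:
                state_el.set("variable", g.state[1])
        if g.clone:
            clone_el = etree.SubElement(el, _qn(SBGN_M2_NS, "clone"))
            if g.clone_label is not None:
                etree.SubElement(clone_el, _qn(SBGN_M2_NS, "label")).set("text", g.clone_label)
        bbox_el = etree.SubElement(el, _qn(SBGN_M2_NS, "bbox"))
        bbox_el.set("x", _num(g.bbox.x))
        bbox_el.set("y", _num(g.bbox.y))
        bbox_el.set("w", _num(g.bbox.w))
        bbox_el.set("h", _num(g.bbox.h))
        for cid in g.children:
            child = pd.glyphs.get(cid)
            if child is not None:
                emit_glyph(child, el)
        for p in g.ports:
            port_el = etree.SubElement(el, _qn(SBGN_M2_NS, "port"))
            port_el.set("id", p.id)
            port_el.set("x", _num(p.position.x))
            port_el.set("y", _num(p.position.y))

    for g in pd.glyphs.values():
        if g.parent is None:
            emit_glyph(g, map_el)

    ports = pd.port_index()

    def anchor_of(ref: str) -> Point:
        if ref in ports:
            return ports[ref].position
        g = pd.glyphs.get(ref)
        return g.bbox.center if g is not None else Point(0.0, 0.0)

    for a in pd.arcs.values():
        el = etree.SubElement(map_el, _qn(SBGN_M2_NS, "arc"))
        el.set("id", a.id)
        el.set("class", a.cls.value)
        el.set("source", a.source)
        el.set("target", a.target)
        _emit_extension(el, a.extension, None)
        start = anchor_of(a.source)
        end = anchor_of(a.target)
        start_el = etree.SubElement(el, _qn(SBGN_M2_NS, "start"))
        start_el.set("x", _num(start.x))
        start_el.set("y", _num(start.y))
        for bend in a.bends:
            next_el = etree.SubElement(el, _qn(SBGN_M2_NS, "next"))
            next_el.set("x", _num(bend.x))
            next_el.set("y", _num(bend.y))
        end_el = etree.SubElement(el, _qn(SBGN_M2_NS, "end"))
        end_el.set("x", _num(end.x))
        end_el.set("y", _num(end.y))

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if isinstance(dest, str):
        with open(dest, "wb") as fh:
            fh.write(data)
    else:
        dest.write(data)


def _emit_extension(el, extension: dict[str, str], multimer_cardinality: Optional[int]) -> None:
    keyed = {k: v for k, v in extension.items() if not k.startswith("raw")}
    raws = [v for k, v in sorted(extension.items()) if k.startswith("raw")]
    if not keyed and not raws and multimer_cardinality is None:
        return
    ext_el = etree.SubElement(el, _qn(SBGN_M2_NS, "extension"))
    if keyed or multimer_cardinality is not None:
        style_el = etree.SubElement(ext_el, _qn(YSBGN_EXT_NS, "style"), nsmap={"ysbgn": YSBGN_EXT_NS})
        for key in sorted(keyed):
            style_el.set(key, keyed[key])
        if multimer_cardinality is not None:
            style_el.set("multimerCardinality", str(multimer_cardinality))
    for raw in raws:
        try:
            ext_el.append(etree.fromstring(raw))
        except etree.XMLSyntaxError:
            note_el = etree.SubElement(ext_el, _qn(YSBGN_EXT_NS, "opaque"), nsmap={"ysbgn": YSBGN_EXT_NS})
            note_el.text = raw


def sbgnml_bytes(pd: PDMap, strict: bool = True) -> bytes:
    buf = io.BytesIO()
    write_sbgnml(pd, buf, strict=strict)
    return buf.getvalue()
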