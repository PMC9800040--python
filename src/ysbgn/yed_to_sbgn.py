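"""Reverse converter: yEd GraphML graph → SBGN PD map.

yEd edges attach directly to the process box; SBGN requires them on one of
the two process ports.  This module implements the reconstruction pipeline:

1. *Reversibility classification* — a process is irreversible when at least
   one consumption and one production arc touch it, reversible when all its
   flux arcs are production arcs.  Modulation-family arcs attach to the
   process body and never participate.
2. *Port assignment* — irreversible: consumption arcs on one port,
   production on the other, consumption's physical side chosen by majority;
   reversible: each arc goes to its nearest port by Euclidean distance from
   the arc position (endpoint or nearest bend) to each candidate port, then
   an empty port is repaired by moving the single farthest arc onto it.
3. *Orientation* — horizontal by default; flipped to vertical when the
   majority of arc positions sit above/below the process, in which case the
   port positions are recomputed on the top/bottom midpoints and the
   assignment re-run once.

After port reconstruction the pipeline detects clone markers (entity pools
drawn more than once) and attaches auxiliary units (state variables, units
of information) to their parent glyphs via the ``aux_refs`` key or, for
hand-drawn files, a geometric boundary-overlap fallback.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .graphml_io import EXT_ATTR_PREFIX
from .pd_model import (
    AUX_CLASSES,
    Arc,
    ArcClass,
    BBox,
    ENTITY_POOL_CLASSES,
    FLUX_ARC_CLASSES,
    Glyph,
    GlyphClass,
    Orientation,
    PDMap,
    Point,
    Port,
    PROCESS_CLASSES,
)
from .report import ConversionReport
from .yed_model import (
    ATTR_CLONE,
    ATTR_CLONE_LABEL,
    ATTR_INVERSE,
    ATTR_MCOUNT,
    ClassificationError,
    YedGraph,
    YedNode,
    edge_class_of,
    node_class_of,
)

#: Default antenna length: how far a port sits outside the process box.
DEFAULT_ANTENNA = 10.0


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    TOP = "top"
    BOTTOM = "bottom"


class Reversibility(str, Enum):
    REVERSIBLE = "reversible"
    IRREVERSIBLE = "irreversible"


class DegenerateProcessError(ValueError):
    """A process whose flux arcs cannot satisfy the port rules as drawn."""


@dataclass(frozen=True)
class ArcAnchor:
    """The 'arc position' of one flux arc relative to a process.

    ``point`` is the bend adjacent to the process end if the edge has bends,
    else the far endpoint (taken as the far node's bbox center).  Distances
    are Euclidean, to the two candidate port positions (port 1 = left/top,
    port 2 = right/bottom).
    """

    arc_id: str
    point: Point
    side: Side
    d_port1: float
    d_port2: float


@dataclass
class PortAssignment:
    process_id: str
    orientation: Orientation
    port1_arcs: list[str]
    port2_arcs: list[str]
    reversible: bool
    repairs: int = 0


def classify_reversibility(incident: Sequence[Arc]) -> Reversibility:
    """Classify a process from its incident arcs.

    Irreversible iff both a consumption and a production arc are present;
    reversible iff all flux arcs are production.  Modulation-family arcs are
    ignored.  All-consumption (or no flux arcs at all) raises
    :class:`DegenerateProcessError` — the caller reports it and falls back to
    a best-effort assignment.
    """
    flux = [a for a in incident if a.cls in FLUX_ARC_CLASSES]
    if not flux:
        raise DegenerateProcessError("process has no flux arcs")
    has_cons = any(a.cls is ArcClass.CONSUMPTION for a in flux)
    has_prod = any(a.cls is ArcClass.PRODUCTION for a in flux)
    if has_cons and has_prod:
        return Reversibility.IRREVERSIBLE
    if has_prod:
        return Reversibility.REVERSIBLE
    raise DegenerateProcessError("all flux arcs are consumption arcs")


def port_positions(bbox: BBox, orientation: Orientation, antenna: float = DEFAULT_ANTENNA) -> tuple[Point, Point]:
    """Candidate port positions: side midpoints offset outward by the antenna length."""
    c = bbox.center
    if orientation is Orientation.HORIZONTAL:
        return (Point(bbox.x - antenna, c.y), Point(bbox.x + bbox.w + antenna, c.y))
    return (Point(c.x, bbox.y - antenna), Point(c.x, bbox.y + bbox.h + antenna))


def arc_anchor(
    arc: Arc,
    process_id: str,
    process_bbox: BBox,
    far_point: Point,
    ports: tuple[Point, Point],
    report: Optional[ConversionReport] = None,
) -> ArcAnchor:
    """Compute the arc position, its side, and its distances to both ports.

    *far_point* is the center of the non-process endpoint's box, used when
    the edge has no bends.  Side is the axis of largest displacement from the
    process center; ties go to left/right (the horizontal bias).
    """
    if arc.bends:
        point = arc.bends[0] if arc.source == process_id else arc.bends[-1]
    else:
        point = far_point
    c = process_bbox.center
    dx, dy = point.x - c.x, point.y - c.y
    if dx == 0 and dy == 0:
        side = Side.LEFT
        if report is not None:
            report.warn("anchor-degenerate", arc.id, "arc position coincides with process center")
    elif abs(dx) >= abs(dy):
        side = Side.LEFT if dx < 0 else Side.RIGHT
    else:
        side = Side.TOP if dy < 0 else Side.BOTTOM
    return ArcAnchor(arc.id, point, side, point.distance_to(ports[0]), point.distance_to(ports[1]))


def compute_orientation(anchors: Iterable[ArcAnchor]) -> Orientation:
    """Majority vote over anchor sides; ties keep the initial horizontal assumption."""
    lr = sum(1 for a in anchors if a.side in (Side.LEFT, Side.RIGHT))
    tb = sum(1 for a in anchors if a.side in (Side.TOP, Side.BOTTOM))
    return Orientation.HORIZONTAL if lr >= tb else Orientation.VERTICAL


def assign_ports_irreversible(
    process_id: str,
    anchors: dict[str, ArcAnchor],
    arcs: Sequence[Arc],
    orientation: Orientation,
    process_center: Point,
) -> PortAssignment:
    """Consumption arcs on one port, production on the other.

    The physical side receiving consumption is the majority side of the
    consumption anchors along the orientation axis; ties (or no informative
    votes) put consumption on port 1 (left/top).
    """
    cons = sorted((a for a in arcs if a.cls is ArcClass.CONSUMPTION), key=lambda a: a.id)
    prod = sorted((a for a in arcs if a.cls is ArcClass.PRODUCTION), key=lambda a: a.id)
    votes = 0
    for a in cons:
        p = anchors[a.id].point
        delta = p.x - process_center.x if orientation is Orientation.HORIZONTAL else p.y - process_center.y
        if delta < 0:
            votes += 1
        elif delta > 0:
            votes -= 1
    cons_on_port1 = votes >= 0
    port1 = [a.id for a in (cons if cons_on_port1 else prod)]
    port2 = [a.id for a in (prod if cons_on_port1 else cons)]
    return PortAssignment(process_id, orientation, port1, port2, reversible=False)


def assign_ports_reversible(
    process_id: str,
    anchors: dict[str, ArcAnchor],
    arcs: Sequence[Arc],
    orientation: Orientation,
) -> PortAssignment:
    """Nearest-port assignment with the single-arc 'farthest' repair.

    Each flux arc goes to the port closest to its arc position (equidistant
    arcs go to port 1).  If one port ends up empty, the arc farthest from
    the occupied port is re-assigned to it, guaranteeing that each port is
    connected to at least one arc.  Requires at least two flux arcs.
    """
    flux = sorted(arcs, key=lambda a: a.id)
    if len(flux) < 2:
        raise DegenerateProcessError("fewer than two flux arcs; port rule 2 unsatisfiable")
    port1: list[str] = []
    port2: list[str] = []
    for a in flux:
        anc = anchors[a.id]
        (port1 if anc.d_port1 <= anc.d_port2 else port2).append(a.id)
    repairs = 0
    if not port2:
        farthest = max(port1, key=lambda aid: (anchors[aid].d_port1, aid))
        port1.remove(farthest)
        port2.append(farthest)
        repairs = 1
    elif not port1:
        farthest = max(port2, key=lambda aid: (anchors[aid].d_port2, aid))
        port2.remove(farthest)
        port1.append(farthest)
        repairs = 1
    return PortAssignment(process_id, orientation, port1, port2, reversible=True, repairs=repairs)


# ---------------------------------------------------------------------------
# clone detection


def _clone_key(g: Glyph, pd: PDMap, per_compartment: bool):
    states = []
    for cid in g.children:
        child = pd.glyphs.get(cid)
        if child is not None and child.cls is GlyphClass.STATE_VARIABLE and child.state is not None:
            states.append(child.state)
    return (
        (g.label or "").strip().casefold(),
        g.cls,
        g.compartment_ref if per_compartment else None,
        g.multimer_cardinality,
        tuple(sorted(states, key=lambda s: (s[0] or "", s[1] or ""))),
    )


def detect_clones(pd: PDMap, per_compartment: bool = True) -> set[str]:
    """Entity pools drawn more than once in the same map.

    Pools sharing (normalized label, class, compartment, multimer
    cardinality, state-variable multiset) in groups of two or more are clone
    markers.  With ``per_compartment=False`` the compartment is ignored, so
    the same species in two compartments counts as cloned.
    """
    groups: dict[tuple, list[str]] = defaultdict(list)
    for g in pd.glyphs.values():
        if g.cls in ENTITY_POOL_CLASSES and (g.label or "").strip():
            groups[_clone_key(g, pd, per_compartment)].append(g.id)
    marked: set[str] = set()
    for members in groups.values():
        if len(members) >= 2:
            marked.update(members)
    return marked


# ---------------------------------------------------------------------------
# auxiliary-unit attachment


def _expand(b: BBox, pad: float) -> tuple[float, float, float, float]:
    return (b.x - pad, b.y - pad, b.x + b.w + pad, b.y + b.h + pad)


def _overlap_area(a: BBox, b: BBox, pad: float) -> float:
    ax0, ay0, ax1, ay1 = _expand(a, pad)
    bx0, by0, bx1, by1 = b.x, b.y, b.x + b.w, b.y + b.h
    w = min(ax1, bx1) - max(ax0, bx0)
    h = min(ay1, by1) - max(ay0, by0)
    return w * h if (w > 0 and h > 0) else 0.0


def find_aux_parent(
    aux: YedNode,
    candidates: Sequence[YedNode],
    pad: float = 5.0,
) -> Optional[str]:
    """Geometric fallback for files without ``aux_refs``.

    The parent is the candidate whose boundary band (bbox expanded by *pad*)
    overlaps the auxiliary node most, ties broken by center distance then id.
    """
    best: Optional[tuple[float, float, str]] = None
    for cand in candidates:
        area = _overlap_area(cand.geometry, aux.geometry, pad)
        if area <= 0:
            continue
        dist = cand.geometry.center.distance_to(aux.geometry.center)
        key = (-area, dist, cand.id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def parse_state_label(label: Optional[str]) -> tuple[Optional[str], Optional[str]]:
    """``"P@Ser15"`` → ``("P", "Ser15")``; a bare label is the value alone."""
    if label is None or label == "":
        return (None, None)
    if "@" in label:
        value, variable = label.split("@", 1)
        return (value or None, variable or None)
    return (label, None)


# ---------------------------------------------------------------------------
# full conversion


def convert(
    graph: YedGraph,
    antenna: float = DEFAULT_ANTENNA,
    clone_policy: str = "per-compartment",
) -> tuple[PDMap, ConversionReport]:
    """Convert a yEd graph to a validate-clean PD map.

    Per-element classification failures are collected in the report and the
    rest of the file is still converted; the function never raises for bad
    content.
    """
    report = ConversionReport()
    pd = PDMap()
    aux_nodes: list[YedNode] = []
    skipped: set[str] = set()

    # -- nodes → glyphs ----------------------------------------------------
    for node in graph.nodes.values():
        try:
            cls = node_class_of(node.style, node.label)
        except ClassificationError as exc:
            report.error("node-class", node.id, str(exc))
            skipped.add(node.id)
            continue
        if cls in AUX_CLASSES:
            aux_nodes.append(node)
            continue
        pd.add_glyph(_make_glyph(node, cls, report))

    # containment: group members get compartment_ref (compartment groups)
    # or parent links (complex groups)
    for node in graph.nodes.values():
        g = pd.glyphs.get(node.id)
        if g is None or not node.parent_group:
            continue
        group = pd.glyphs.get(node.parent_group)
        if group is None:
            continue
        if group.cls is GlyphClass.COMPARTMENT:
            g.compartment_ref = group.id
        elif group.cls is GlyphClass.COMPLEX:
            g.parent = group.id
            group.children.append(g.id)

    # -- auxiliary units ---------------------------------------------------
    aux_parent: dict[str, str] = {}
    for node in graph.nodes.values():
        for ref in node.aux_refs:
            aux_parent[ref] = node.id
    candidates = [
        n for n in graph.nodes.values()
        if n.id in pd.glyphs and pd.glyphs[n.id].cls in (ENTITY_POOL_CLASSES | PROCESS_CLASSES | {GlyphClass.SUBMAP})
    ]
    for aux in aux_nodes:
        cls = node_class_of(aux.style, aux.label)
        parent_id = aux_parent.get(aux.id)
        if parent_id is None or parent_id not in pd.glyphs:
            parent_id = find_aux_parent(aux, candidates)
            if parent_id is not None:
                report.notify("aux-geometric", aux.id, f"attached to {parent_id!r} by boundary overlap")
        g = Glyph(id=aux.id, cls=cls, bbox=aux.geometry)
        if cls is GlyphClass.STATE_VARIABLE:
            g.state = parse_state_label(aux.label)
        else:
            g.label = aux.label
        _carry_style_extension(aux, g)
        if parent_id is None:
            report.warn("aux-orphan", aux.id, "no parent found; emitted as standalone glyph")
        else:
            parent = pd.glyphs[parent_id]
            g.parent = parent_id
            parent.children.append(g.id)
        pd.add_glyph(g)

    # -- edges → arcs ------------------------------------------------------
    for edge in graph.edges.values():
        if edge.source in skipped or edge.target in skipped:
            report.error("edge-skip", edge.id, "endpoint node failed to classify")
            continue
        if edge.source not in pd.glyphs or edge.target not in pd.glyphs:
            report.error("edge-skip", edge.id, "endpoint does not resolve to a glyph")
            continue
        try:
            cls = edge_class_of(edge.style)
        except ClassificationError as exc:
            report.error("edge-class", edge.id, str(exc))
            continue
        arc = Arc(id=edge.id, cls=cls, source=edge.source, target=edge.target, bends=list(edge.bends))
        if edge.style.colour:
            arc.extension["stroke"] = edge.style.colour
        pd.add_arc(arc)

    # -- process port reconstruction --------------------------------------
    incidence: dict[str, list[Arc]] = defaultdict(list)
    for a in pd.arcs.values():
        incidence[a.source].append(a)
        if a.target != a.source:
            incidence[a.target].append(a)
    for g in list(pd.glyphs.values()):
        if g.cls in PROCESS_CLASSES:
            _reconstruct_ports(pd, g, incidence.get(g.id, []), antenna, report)

    # -- clone markers -----------------------------------------------------
    marked = detect_clones(pd, per_compartment=(clone_policy == "per-compartment"))
    for gid in marked:
        pd.glyphs[gid].clone = True

    return pd, report


def _make_glyph(node: YedNode, cls: GlyphClass, report: ConversionReport) -> Glyph:
    g = Glyph(id=node.id, cls=cls, bbox=node.geometry)
    # marker labels ("\\\\", "?", AND/OR/NOT) are class encodings, not labels
    if cls not in PROCESS_CLASSES and cls not in (GlyphClass.AND, GlyphClass.OR, GlyphClass.NOT):
        g.label = node.label
    elif cls is GlyphClass.PROCESS:
        g.label = node.label or None
    if cls is GlyphClass.TAG:
        g.orientation = Orientation.RIGHT if node.style.inverse else Orientation.LEFT
    mcount = node.style.style_attrs.get(ATTR_MCOUNT)
    if mcount is not None:
        try:
            g.multimer_cardinality = int(mcount)
        except ValueError:
            report.warn("mcount", node.id, f"unparseable mcount {mcount!r}")
    if node.style.clone:
        g.clone = True
        g.clone_label = node.style.style_attrs.get(ATTR_CLONE_LABEL)
    _carry_style_extension(node, g)
    return g


def _carry_style_extension(node: YedNode, g: Glyph) -> None:
    for key, value in node.style.style_attrs.items():
        if key in ("fill", "stroke"):
            g.extension[key] = value
        elif key.startswith(EXT_ATTR_PREFIX):
            g.extension[key[len(EXT_ATTR_PREFIX):]] = value


def _reconstruct_ports(
    pd: PDMap, g: Glyph, incident: Sequence[Arc], antenna: float, report: ConversionReport
) -> None:
    incident = sorted(incident, key=lambda a: a.id)
    flux = [a for a in incident if a.cls in FLUX_ARC_CLASSES]
    # flux arcs between two processes cannot be attributed to a single port pair
    flux = [
        a for a in flux
        if not (
            pd.glyphs.get(a.source if a.target == g.id else a.target) is not None
            and pd.glyphs[a.source if a.target == g.id else a.target].cls in PROCESS_CLASSES
        )
    ]
    try:
        reversibility = classify_reversibility(flux)
        best_effort = False
    except DegenerateProcessError as exc:
        if len(flux) >= 2:
            # all-consumption: fall back to the reversible-style assignment
            report.error("degenerate-process", g.id, f"{exc}; best-effort port assignment applied")
            reversibility = Reversibility.REVERSIBLE
            best_effort = True
        else:
            if flux:
                report.error("degenerate-process", g.id, f"{exc}; process emitted without ports")
            else:
                report.warn("no-flux-arcs", g.id, "process has no flux arcs; emitted without ports")
            return
    if len(flux) < 2:
        report.error("degenerate-process", g.id, "single flux arc; port rule 2 unsatisfiable, no ports emitted")
        return

    def far_point(a: Arc) -> Point:
        other = a.source if a.target == g.id else a.target
        og = pd.glyphs.get(other)
        return og.bbox.center if og is not None else g.bbox.center

    def anchors_for(orientation: Orientation) -> dict[str, ArcAnchor]:
        ports = port_positions(g.bbox, orientation, antenna)
        return {
            a.id: arc_anchor(a, g.id, g.bbox, far_point(a), ports, report)
            for a in flux
        }

    anchors = anchors_for(Orientation.HORIZONTAL)
    orientation = compute_orientation(anchors.values())
    if orientation is Orientation.VERTICAL:
        anchors = anchors_for(Orientation.VERTICAL)  # re-run with top/bottom ports
        report.notify("orientation-flip", g.id, "vertical orientation inferred; assignment re-run")

    if reversibility is Reversibility.IRREVERSIBLE:
        assignment = assign_ports_irreversible(g.id, anchors, flux, orientation, g.bbox.center)
    else:
        assignment = assign_ports_reversible(g.id, anchors, flux, orientation)
    if assignment.repairs:
        report.notify("port-repair", g.id, f"{assignment.repairs} arc re-assigned to an empty port")
    if best_effort:
        assignment.reversible = False

    g.orientation = orientation
    pos1, pos2 = port_positions(g.bbox, orientation, antenna)
    p1 = Port(id=f"{g.id}.1", position=pos1, owner=g.id)
    p2 = Port(id=f"{g.id}.2", position=pos2, owner=g.id)
    g.ports = [p1, p2]

    arc_by_id = {a.id: a for a in flux}
    for port, arc_ids in ((p1, assignment.port1_arcs), (p2, assignment.port2_arcs)):
        for aid in arc_ids:
            _rewire(arc_by_id[aid], g.id, port.id, report)


def _rewire(arc: Arc, process_id: str, port_id: str, report: ConversionReport) -> None:
    """Attach the process end of a flux arc to a port, normalizing direction.

    Consumption must run entity→port, production port→entity; arcs drawn the
    other way round are flipped with a warning.
    """
    if arc.source == process_id:
        arc.source = port_id
    else:
        arc.target = port_id
    if arc.cls is ArcClass.CONSUMPTION and arc.source == port_id:
        arc.source, arc.target = arc.target, arc.source
        arc.bends.reverse()
        report.warn("arc-direction", arc.id, "consumption arc drawn out of the process; flipped")
    elif arc.cls is ArcClass.PRODUCTION and arc.target == port_id:
        arc.source, arc.target = arc.target, arc.source
        arc.bends.reverse()
        report.warn("arc-direction", arc.id, "production arc drawn into the process; flipped")
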