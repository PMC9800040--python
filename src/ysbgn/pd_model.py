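"""In-memory model of an SBGN Process Description map.

The PD language draws a biochemical network as *glyphs* (entity pools,
processes, operators, compartments, auxiliary units) connected by *arcs*
(consumption, production and the modulation family).  Process glyphs carry two
*ports* — the antenna tips where consumption/production arcs attach — which
separate the two sides of the reaction equation.

This module is the hub both converters read from and write to.  It knows the
PD validity rules that matter for conversion:

1. all arcs attached to one port must have the same class, and
2. every port of a process must be connected to at least one arc.

Violations are data (:class:`Violation` records), never exceptions: a map
drawn by hand is allowed to be broken, and the converter's job is to repair
and report, not to crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class GlyphClass(str, Enum):
    """Closed enumeration of the PD node classes handled by the converter."""

    COMPARTMENT = "compartment"
    COMPLEX = "complex"
    MACROMOLECULE = "macromolecule"
    NUCLEIC_ACID_FEATURE = "nucleic acid feature"
    SIMPLE_CHEMICAL = "simple chemical"
    UNSPECIFIED_ENTITY = "unspecified entity"
    PERTURBING_AGENT = "perturbing agent"
    PHENOTYPE = "phenotype"
    SOURCE_AND_SINK = "source and sink"
    PROCESS = "process"
    OMITTED_PROCESS = "omitted process"
    UNCERTAIN_PROCESS = "uncertain process"
    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    AND = "and"
    OR = "or"
    NOT = "not"
    SUBMAP = "submap"
    TAG = "tag"
    STATE_VARIABLE = "state variable"
    UNIT_OF_INFORMATION = "unit of information"


#: Glyph classes that behave as a process (square box with two ports).
PROCESS_CLASSES = frozenset(
    {
        GlyphClass.PROCESS,
        GlyphClass.OMITTED_PROCESS,
        GlyphClass.UNCERTAIN_PROCESS,
        GlyphClass.ASSOCIATION,
        GlyphClass.DISSOCIATION,
    }
)

#: Entity-pool classes (the things clone markers apply to).
ENTITY_POOL_CLASSES = frozenset(
    {
        GlyphClass.MACROMOLECULE,
        GlyphClass.SIMPLE_CHEMICAL,
        GlyphClass.NUCLEIC_ACID_FEATURE,
        GlyphClass.COMPLEX,
        GlyphClass.UNSPECIFIED_ENTITY,
        GlyphClass.PERTURBING_AGENT,
        GlyphClass.SOURCE_AND_SINK,
    }
)

#: Classes that may carry a multimer cardinality.
MULTIMER_CLASSES = frozenset(
    {
        GlyphClass.SIMPLE_CHEMICAL,
        GlyphClass.MACROMOLECULE,
        GlyphClass.COMPLEX,
        GlyphClass.NUCLEIC_ACID_FEATURE,
    }
)

#: Auxiliary units drawn on the border of a parent glyph.
AUX_CLASSES = frozenset({GlyphClass.STATE_VARIABLE, GlyphClass.UNIT_OF_INFORMATION})

LOGIC_CLASSES = frozenset({GlyphClass.AND, GlyphClass.OR, GlyphClass.NOT})


class ArcClass(str, Enum):
    CONSUMPTION = "consumption"
    PRODUCTION = "production"
    CATALYSIS = "catalysis"
    STIMULATION = "stimulation"
    INHIBITION = "inhibition"
    MODULATION = "modulation"
    NECESSARY_STIMULATION = "necessary stimulation"


#: Flux arcs attach to process ports; modulation-family arcs attach to the body.
FLUX_ARC_CLASSES = frozenset({ArcClass.CONSUMPTION, ArcClass.PRODUCTION})


class Orientation(str, Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"
    LEFT = "left"
    RIGHT = "right"
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, top-left origin, y grows downward (shared by both formats)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"bbox with non-positive extent w={self.w} h={self.h}")

    @property
    def center(self) -> Point:
        return Point(self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class Port:
    id: str
    position: Point
    owner: str  # id of the owning process glyph


@dataclass
class Glyph:
    id: str
    cls: GlyphClass
    bbox: BBox
    label: Optional[str] = None
    compartment_ref: Optional[str] = None
    parent: Optional[str] = None
    clone: bool = False
    clone_label: Optional[str] = None
    multimer_cardinality: Optional[int] = None
    state: Optional[tuple[Optional[str], Optional[str]]] = None  # (value, variable)
    orientation: Optional[Orientation] = None
    ports: list[Port] = field(default_factory=list)
    children: list[str] = field(default_factory=list)
    extension: dict[str, str] = field(default_factory=dict)


@dataclass
class Arc:
    id: str
    cls: ArcClass
    source: str  # glyph id or port id
    target: str
    bends: list[Point] = field(default_factory=list)
    extension: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    rule: str
    element: str
    message: str


@dataclass
class PDMap:
    """A Process Description map: flat glyph and arc stores with id references."""

    language: str = "process description"
    glyphs: dict[str, Glyph] = field(default_factory=dict)
    arcs: dict[str, Arc] = field(default_factory=dict)

    def add_glyph(self, glyph: Glyph) -> Glyph:
        self.glyphs[glyph.id] = glyph
        return glyph

    def add_arc(self, arc: Arc) -> Arc:
        self.arcs[arc.id] = arc
        return arc

    def iter_ports(self) -> Iterator[Port]:
        for g in self.glyphs.values():
            yield from g.ports

    def port_index(self) -> dict[str, Port]:
        return {p.id: p for p in self.iter_ports()}

    def resolve(self, ref: str) -> Glyph | Port | None:
        if ref in self.glyphs:
            return self.glyphs[ref]
        return self.port_index().get(ref)

    def endpoint_glyph(self, ref: str) -> Optional[Glyph]:
        """The glyph behind an arc endpoint, collapsing port ids to their owner."""
        obj = self.resolve(ref)
        if isinstance(obj, Port):
            return self.glyphs.get(obj.owner)
        return obj


def incident_arcs(pd: PDMap, process_id: str) -> list[Arc]:
    """Arcs touching a process glyph or any of its ports, in stable arc-id order."""
    glyph = pd.glyphs.get(process_id)
    if glyph is None:
        raise KeyError(f"unknown glyph id {process_id!r}")
    ids = {process_id} | {p.id for p in glyph.ports}
    hits = [a for a in pd.arcs.values() if a.source in ids or a.target in ids]
    hits.sort(key=lambda a: a.id)
    return hits


def validate(pd: PDMap) -> list[Violation]:
    """Check a map against the PD invariants the converter relies on.

    Pure and idempotent; returns one record per violated invariant.  An empty
    list means the map is PD-valid under the conversion rules.
    """
    out: list[Violation] = []
    ports = {}
    seen: set[str] = set()

    def claim(eid: str, what: str) -> None:
        if eid in seen:
            out.append(Violation("dup-id", eid, f"duplicate id on {what}"))
        seen.add(eid)

    for g in pd.glyphs.values():
        claim(g.id, "glyph")
        for p in g.ports:
            claim(p.id, "port")
            ports[p.id] = p
            if p.owner != g.id:
                out.append(Violation("port-owner", p.id, "port owner mismatch"))
    for a in pd.arcs.values():
        claim(a.id, "arc")

    for g in pd.glyphs.values():
        if g.compartment_ref is not None:
            comp = pd.glyphs.get(g.compartment_ref)
            if comp is None:
                out.append(
                    Violation("ref-resolve", g.id, f"compartmentRef {g.compartment_ref!r} does not resolve")
                )
            elif comp.cls is not GlyphClass.COMPARTMENT:
                out.append(
                    Violation("ref-resolve", g.id, f"compartmentRef {g.compartment_ref!r} is not a compartment")
                )
        if g.parent is not None and g.parent not in pd.glyphs:
            out.append(Violation("ref-resolve", g.id, f"parent {g.parent!r} does not resolve"))
        for cid in g.children:
            child = pd.glyphs.get(cid)
            if child is None:
                out.append(Violation("ref-resolve", g.id, f"child {cid!r} does not resolve"))
            elif g.cls not in (GlyphClass.COMPLEX, GlyphClass.COMPARTMENT, GlyphClass.SUBMAP):
                if child.cls not in AUX_CLASSES:
                    out.append(
                        Violation(
                            "child-class", g.id,
                            f"non-container glyph holds non-auxiliary child {cid!r} ({child.cls.value})",
                        )
                    )
        if g.multimer_cardinality is not None:
            if g.cls not in MULTIMER_CLASSES:
                out.append(Violation("multimer-class", g.id, f"{g.cls.value} cannot be a multimer"))
            elif g.multimer_cardinality < 2:
                out.append(Violation("multimer-card", g.id, "multimer cardinality must be >= 2"))
        if (g.state is not None) != (g.cls is GlyphClass.STATE_VARIABLE):
            out.append(Violation("state-class", g.id, "state present iff glyph is a state variable"))
        if g.ports and g.cls not in PROCESS_CLASSES:
            out.append(Violation("port-class", g.id, f"{g.cls.value} glyph carries ports"))
        if g.cls in PROCESS_CLASSES and len(g.ports) not in (0, 2):
            out.append(Violation("port-count", g.id, f"process has {len(g.ports)} ports (expected 0 or 2)"))

    arcs_by_port: dict[str, list[Arc]] = {pid: [] for pid in ports}
    for a in pd.arcs.values():
        if a.source == a.target:
            out.append(Violation("self-loop", a.id, "arc source equals target"))
        for ref in (a.source, a.target):
            if ref not in pd.glyphs and ref not in ports:
                out.append(Violation("ref-resolve", a.id, f"endpoint {ref!r} does not resolve"))
            elif ref in ports:
                arcs_by_port[ref].append(a)
        # PD convention: consumption points entity->port, production port->entity
        if a.cls is ArcClass.CONSUMPTION and a.source in ports:
            out.append(Violation("arc-direction", a.id, "consumption arc leaves a port"))
        if a.cls is ArcClass.PRODUCTION and a.target in ports:
            out.append(Violation("arc-direction", a.id, "production arc enters a port"))

    for pid, attached in arcs_by_port.items():
        classes = {a.cls for a in attached}
        if len(classes) > 1:
            out.append(
                Violation(
                    "port-rule-1", pid,
                    "arcs connected to the same port must have the same class: "
                    + ", ".join(sorted(c.value for c in classes)),
                )
            )
        if not attached:
            out.append(Violation("port-rule-2", pid, "port has no connected arc"))

    return out
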