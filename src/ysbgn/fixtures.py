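"""Deterministic synthetic-map generator.

Produces PD maps (and their yEd counterparts) that exercise every conversion
path: reversible and irreversible processes in both orientations,
compartments, complexes with members, multimers, clone markers, auxiliary
units, modulation arcs and — on request — the degradation-prone elements
(association/dissociation processes, up/down tags).  Geometry is laid out on
a jittered grid so every arc position has an unambiguous side relative to
its process; anchor ties only occur in fixtures built explicitly for them.

The same spec and seed always produce the same map, byte-for-byte after
serialization, so generated fixtures double as regression anchors.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass

from .pd_model import (
    Arc,
    ArcClass,
    BBox,
    Glyph,
    GlyphClass,
    MULTIMER_CLASSES,
    Orientation,
    PDMap,
    Point,
    Port,
)
from .yed_model import (
    ArrowType,
    CONFIG_PROCESS,
    CONFIG_SIMPLE_CHEMICAL,
    YedEdge,
    YedEdgeStyle,
    YedGraph,
    YedNode,
    YedNodeStyle,
)
from . import sbgn_to_yed
from .yed_to_sbgn import DEFAULT_ANTENNA, detect_clones, port_positions

_CELL_W, _CELL_H = 420.0, 360.0
_PROC_SIZE = 20.0

_ENTITY_CLASSES = [
    (GlyphClass.SIMPLE_CHEMICAL, 0.40),
    (GlyphClass.MACROMOLECULE, 0.30),
    (GlyphClass.NUCLEIC_ACID_FEATURE, 0.10),
    (GlyphClass.UNSPECIFIED_ENTITY, 0.08),
    (GlyphClass.COMPLEX, 0.07),
    (GlyphClass.SOURCE_AND_SINK, 0.05),
]

_MODULATION_CLASSES = [
    ArcClass.CATALYSIS,
    ArcClass.STIMULATION,
    ArcClass.INHIBITION,
    ArcClass.MODULATION,
    ArcClass.NECESSARY_STIMULATION,
]


@dataclass(frozen=True)
class FixtureSpec:
    n_compartments: int = 0
    n_pools: int = 8
    n_processes: int = 4
    reversible_fraction: float = 0.3
    clone_fraction: float = 0.15
    aux_unit_fraction: float = 0.2
    multimer_fraction: float = 0.1
    modulation_fraction: float = 0.25
    degradation_elements: bool = False
    seed: int = 0
    canvas: BBox = BBox(0.0, 0.0, 1e6, 1e6)

    def __post_init__(self) -> None:
        for name in (
            "reversible_fraction", "clone_fraction", "aux_unit_fraction",
            "multimer_fraction", "modulation_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_compartments < 0 or self.n_pools < 0 or self.n_processes < 0:
            raise ValueError("counts must be >= 0")


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.pd = PDMap()
        self.n_glyph = 0
        self.n_arc = 0
        self.used_labels: list[str] = []
        self.n_label = 0

    def gid(self, prefix: str = "g") -> str:
        self.n_glyph += 1
        return f"{prefix}{self.n_glyph:05d}"

    def aid(self) -> str:
        self.n_arc += 1
        return f"a{self.n_arc:05d}"

    def next_label(self) -> str:
        if self.used_labels and self.rng.random() < self.spec.clone_fraction:
            return self.rng.choice(self.used_labels)
        self.n_label += 1
        label = f"S{self.n_label}"
        self.used_labels.append(label)
        return label

    def pick_entity_class(self) -> GlyphClass:
        r = self.rng.random()
        acc = 0.0
        for cls, w in _ENTITY_CLASSES:
            acc += w
            if r < acc:
                return cls
        return GlyphClass.SIMPLE_CHEMICAL

    def make_entity(self, cx: float, cy: float, compartment: str | None) -> Glyph:
        cls = self.pick_entity_class()
        if cls is GlyphClass.COMPLEX:
            w, h = 110.0, 70.0
        elif cls is GlyphClass.SIMPLE_CHEMICAL:
            w, h = 60.0, 40.0
        else:
            w, h = 80.0, 40.0
        g = Glyph(
            id=self.gid(),
            cls=cls,
            bbox=BBox(cx - w / 2, cy - h / 2, w, h),
            compartment_ref=compartment,
        )
        if cls is not GlyphClass.SOURCE_AND_SINK:
            g.label = self.next_label()
        if cls in MULTIMER_CLASSES and self.rng.random() < self.spec.multimer_fraction:
            g.multimer_cardinality = self.rng.randint(2, 4)
        self.pd.add_glyph(g)
        if cls is GlyphClass.COMPLEX:
            for k in range(self.rng.randint(1, 2)):
                self.n_label += 1
                member = Glyph(
                    id=self.gid("m"),
                    cls=GlyphClass.MACROMOLECULE,
                    bbox=BBox(g.bbox.x + 8 + k * 50, g.bbox.y + 22, 42.0, 22.0),
                    label=f"U{self.n_label}",
                    parent=g.id,
                )
                self.pd.add_glyph(member)
                g.children.append(member.id)
        if cls in (GlyphClass.MACROMOLECULE, GlyphClass.NUCLEIC_ACID_FEATURE, GlyphClass.COMPLEX):
            if self.rng.random() < self.spec.aux_unit_fraction:
                self.add_aux(g)
        return g

    def add_aux(self, parent: Glyph) -> None:
        kind = self.rng.random()
        if kind < 0.6:
            sv = Glyph(
                id=self.gid("sv"),
                cls=GlyphClass.STATE_VARIABLE,
                bbox=BBox(parent.bbox.x + 10, parent.bbox.y - 7, 24.0, 14.0),
                parent=parent.id,
                state=(
                    self.rng.choice(["P", "Ub", "Me", "Ac"]),
                    f"Ser{self.rng.randint(1, 400)}" if self.rng.random() < 0.7 else None,
                ),
            )
            self.pd.add_glyph(sv)
            parent.children.append(sv.id)
        else:
            ui = Glyph(
                id=self.gid("ui"),
                cls=GlyphClass.UNIT_OF_INFORMATION,
                bbox=BBox(parent.bbox.x + parent.bbox.w - 34, parent.bbox.y - 7, 24.0, 14.0),
                parent=parent.id,
                label=self.rng.choice(["mt:prot", "ct:gene", "mt:rna"]),
            )
            self.pd.add_glyph(ui)
            parent.children.append(ui.id)

    def jitter(self, amount: float = 12.0) -> float:
        return self.rng.uniform(-amount, amount)


def generate_pd(spec: FixtureSpec) -> PDMap:
    """Generate a validate-clean PD map from a fixture spec.

    Every process carries two ports; irreversible processes have 1–3
    consumption and 1–3 production arcs, reversible ones 2–4 production arcs
    split over both ports.  Entity glyph labels recur with probability
    ``clone_fraction`` and all members of the resulting duplicate groups are
    clone-marked with the same key the reverse converter's detector uses.
    If fewer entity glyphs than ``n_pools`` were needed, standalone pools
    top the map up to ``n_pools``.
    """
    b = _Builder(spec)
    rng = b.rng
    cols = max(1, int(spec.n_processes ** 0.5 + 0.5))
    comp_ids: list[str | None] = []
    if spec.n_compartments > 0:
        for _ in range(spec.n_compartments):
            comp_ids.append(b.gid("c"))
    comp_members: dict[str, list[str]] = {c: [] for c in comp_ids if c is not None}

    x0 = spec.canvas.x + 200.0
    y0 = spec.canvas.y + 200.0
    n_entities = 0
    rows_used = 0

    for i in range(spec.n_processes):
        col, row = i % cols, i // cols
        rows_used = max(rows_used, row + 1)
        px = x0 + col * _CELL_W + b.jitter()
        py = y0 + row * _CELL_H + b.jitter()
        comp = comp_ids[col * spec.n_compartments // cols] if comp_ids else None

        cls = GlyphClass.PROCESS
        if spec.degradation_elements and rng.random() < 0.2:
            cls = rng.choice([GlyphClass.ASSOCIATION, GlyphClass.DISSOCIATION])
        elif rng.random() < 0.15:
            cls = rng.choice([GlyphClass.OMITTED_PROCESS, GlyphClass.UNCERTAIN_PROCESS])
        vertical = rng.random() < 0.3
        proc = Glyph(
            id=b.gid("pr"),
            cls=cls,
            bbox=BBox(px - _PROC_SIZE / 2, py - _PROC_SIZE / 2, _PROC_SIZE, _PROC_SIZE),
            compartment_ref=comp,
            orientation=Orientation.VERTICAL if vertical else Orientation.HORIZONTAL,
        )
        b.pd.add_glyph(proc)
        if comp is not None:
            comp_members[comp].append(proc.id)

        pos1, pos2 = port_positions(proc.bbox, proc.orientation, DEFAULT_ANTENNA)
        p1 = Port(id=f"{proc.id}.1", position=pos1, owner=proc.id)
        p2 = Port(id=f"{proc.id}.2", position=pos2, owner=proc.id)
        proc.ports = [p1, p2]

        def place(side_index: int, k: int, total: int) -> tuple[float, float]:
            # side_index 0 = left/top (port 1), 1 = right/bottom (port 2)
            spread = (k - (total - 1) / 2.0) * 60.0 + b.jitter(8.0)
            main = 160.0 + (k % 2) * 35.0 + b.jitter(8.0)
            if vertical:
                return (px + spread, py - main if side_index == 0 else py + main)
            return (px - main if side_index == 0 else px + main, py + spread)

        reversible = rng.random() < spec.reversible_fraction
        if reversible:
            total = rng.randint(2, 4)
            n_side1 = rng.randint(1, total - 1)
            counts = (n_side1, total - n_side1)
            for side_index, port in ((0, p1), (1, p2)):
                for k in range(counts[side_index]):
                    ex, ey = place(side_index, k, counts[side_index])
                    ent = b.make_entity(ex, ey, comp)
                    n_entities += 1
                    if comp is not None:
                        comp_members[comp].append(ent.id)
                    b.pd.add_arc(Arc(id=b.aid(), cls=ArcClass.PRODUCTION, source=port.id, target=ent.id))
        else:
            n_cons, n_prod = rng.randint(1, 3), rng.randint(1, 3)
            for k in range(n_cons):
                ex, ey = place(0, k, n_cons)
                ent = b.make_entity(ex, ey, comp)
                n_entities += 1
                if comp is not None:
                    comp_members[comp].append(ent.id)
                b.pd.add_arc(Arc(id=b.aid(), cls=ArcClass.CONSUMPTION, source=ent.id, target=p1.id))
            for k in range(n_prod):
                ex, ey = place(1, k, n_prod)
                ent = b.make_entity(ex, ey, comp)
                n_entities += 1
                if comp is not None:
                    comp_members[comp].append(ent.id)
                b.pd.add_arc(Arc(id=b.aid(), cls=ArcClass.PRODUCTION, source=p2.id, target=ent.id))

        if rng.random() < spec.modulation_fraction:
            # modulator sits diagonally off the process; modulation arcs hit the body
            mx = px + rng.choice([-1.0, 1.0]) * (120.0 + b.jitter(8.0))
            my = py + (-1.0 if not vertical else 1.0) * (120.0 + b.jitter(8.0))
            mod = b.make_entity(mx + (0.0 if vertical else 0.0), my, comp)
            n_entities += 1
            if comp is not None:
                comp_members[comp].append(mod.id)
            b.pd.add_arc(
                Arc(id=b.aid(), cls=rng.choice(_MODULATION_CLASSES), source=mod.id, target=proc.id)
            )

    # standalone pools to reach n_pools entity glyphs
    extra_row = rows_used + 1
    k = 0
    while n_entities < spec.n_pools:
        ex = x0 + (k % max(cols, 1)) * _CELL_W + b.jitter()
        ey = y0 + (extra_row + k // max(cols, 1)) * _CELL_H + b.jitter()
        comp = comp_ids[(k % max(cols, 1)) * spec.n_compartments // cols] if comp_ids else None
        ent = b.make_entity(ex, ey, comp)
        if comp is not None:
            comp_members[comp].append(ent.id)
        n_entities += 1
        k += 1

    if spec.degradation_elements:
        for k in range(rng.randint(1, 2)):
            tag = Glyph(
                id=b.gid("t"),
                cls=GlyphClass.TAG,
                bbox=BBox(x0 + k * 120.0, y0 - 160.0, 60.0, 30.0),
                label=f"T{k + 1}",
                orientation=rng.choice(
                    [Orientation.LEFT, Orientation.RIGHT, Orientation.UP, Orientation.DOWN]
                ),
            )
            b.pd.add_glyph(tag)

    # compartment boxes wrap their members with a margin
    for comp_id in comp_ids:
        members = comp_members.get(comp_id, [])
        if members:
            xs0 = min(b.pd.glyphs[m].bbox.x for m in members) - 40.0
            ys0 = min(b.pd.glyphs[m].bbox.y for m in members) - 40.0
            xs1 = max(b.pd.glyphs[m].bbox.x + b.pd.glyphs[m].bbox.w for m in members) + 40.0
            ys1 = max(b.pd.glyphs[m].bbox.y + b.pd.glyphs[m].bbox.h for m in members) + 40.0
        else:
            xs0, ys0, xs1, ys1 = (0.0, -700.0, 300.0, -500.0)
        comp = Glyph(
            id=comp_id,
            cls=GlyphClass.COMPARTMENT,
            bbox=BBox(xs0, ys0, xs1 - xs0, ys1 - ys0),
            label=f"compartment {comp_id}",
        )
        b.pd.add_glyph(comp)

    # colours exercise the extension round trip
    for g in b.pd.glyphs.values():
        if g.cls in (GlyphClass.SIMPLE_CHEMICAL, GlyphClass.MACROMOLECULE) and rng.random() < 0.3:
            g.extension["fill"] = "#%06X" % rng.randint(0, 0xFFFFFF)
            g.extension["stroke"] = "#333333"

    for gid_ in detect_clones(b.pd):
        b.pd.glyphs[gid_].clone = True
    return b.pd


def strip_ports(pd: PDMap) -> PDMap:
    """Collapse all process ports onto the process glyphs (yEd-style attachment)."""
    out = copy.deepcopy(pd)
    owner = {p.id: p.owner for p in out.iter_ports()}
    for g in out.glyphs.values():
        g.ports = []
        g.orientation = g.orientation if g.cls is GlyphClass.TAG else None
    for a in out.arcs.values():
        a.source = owner.get(a.source, a.source)
        a.target = owner.get(a.target, a.target)
    return out


def generate_yed(spec: FixtureSpec) -> YedGraph:
    """Generate the yEd counterpart of :func:`generate_pd`.

    Edges attach directly to the process boxes — no ports, no port bends —
    so the reverse converter's reconstruction algorithms are genuinely
    exercised rather than replayed.
    """
    graph, _report = sbgn_to_yed.convert(strip_ports(generate_pd(spec)))
    return graph


def random_process_graph(seed: int, max_flux: int = 8) -> YedGraph:
    """A single-process stress graph: 1–``max_flux`` flux edges, arbitrary mix.

    Edge classes, entity angles and drawing directions are all random, so
    this exercises the degenerate paths (single flux arc, all-consumption)
    and the direction-normalization logic that the grid fixtures avoid by
    construction.  Bends are occasionally inserted so the nearest-bend rule
    of the arc-position definition is hit too.
    """
    rng = random.Random(seed)
    g = YedGraph()
    px, py = 300.0, 300.0
    _process(g, "P", px - 10.0, py - 10.0)
    n_flux = rng.randint(1, max_flux)
    for k in range(n_flux):
        angle = rng.uniform(0.0, 360.0)
        dist = rng.uniform(90.0, 220.0)
        ex = px + dist * math.cos(math.radians(angle))
        ey = py + dist * math.sin(math.radians(angle))
        ent = _entity(g, f"E{k:02d}", ex - 30.0, ey - 20.0, f"M{k}")
        production = rng.random() < 0.5
        if production:
            edge = _edge(g, f"e{k:02d}", "P", ent.id, production=True)
        else:
            # consumption lines are drawn in either direction by hand
            if rng.random() < 0.5:
                edge = _edge(g, f"e{k:02d}", ent.id, "P", production=False)
            else:
                edge = _edge(g, f"e{k:02d}", "P", ent.id, production=False)
        if rng.random() < 0.3:
            edge.bends.append(Point(px + (ex - px) * 0.4, py + (ey - py) * 0.4))
    if rng.random() < 0.3:
        cat = _entity(g, "CAT", px - 30.0, py - 180.0, "enzyme")
        g.add_edge(
            YedEdge(
                id="ecat",
                source=cat.id,
                target="P",
                style=YedEdgeStyle(source_arrow=ArrowType.NONE, target_arrow=ArrowType.CIRCLE),
            )
        )
    return g


# ---------------------------------------------------------------------------
# hand-built preset scenarios: reversible, irreversible horizontal/vertical


def _entity(graph: YedGraph, nid: str, x: float, y: float, label: str) -> YedNode:
    return graph.add_node(
        YedNode(
            id=nid,
            geometry=BBox(x, y, 60.0, 40.0),
            style=YedNodeStyle(configuration=CONFIG_SIMPLE_CHEMICAL),
            label=label,
        )
    )


def _process(graph: YedGraph, nid: str, x: float, y: float) -> YedNode:
    return graph.add_node(
        YedNode(id=nid, geometry=BBox(x, y, 20.0, 20.0), style=YedNodeStyle(configuration=CONFIG_PROCESS))
    )


def _edge(graph: YedGraph, eid: str, src: str, tgt: str, production: bool) -> YedEdge:
    style = YedEdgeStyle(
        source_arrow=ArrowType.NONE,
        target_arrow=ArrowType.STANDARD if production else ArrowType.NONE,
    )
    return graph.add_edge(YedEdge(id=eid, source=src, target=tgt, style=style))


def fig2_fixtures() -> dict[str, YedGraph]:
    """The three canonical process-conversion scenarios.

    ``reversible``: two production edges leaving the process to its left and
    right; ``irreversible_horizontal``: two consumptions from the left, one
    production to the right; ``irreversible_vertical``: consumptions from
    above, production below.
    """
    out: dict[str, YedGraph] = {}

    g = YedGraph()
    _process(g, "P", 200.0, 200.0)
    _entity(g, "E1", 60.0, 190.0, "A")
    _entity(g, "E2", 300.0, 190.0, "B")
    _edge(g, "e1", "P", "E1", production=True)
    _edge(g, "e2", "P", "E2", production=True)
    out["reversible"] = g

    g = YedGraph()
    _process(g, "P", 200.0, 200.0)
    _entity(g, "E1", 40.0, 140.0, "A")
    _entity(g, "E2", 40.0, 250.0, "B")
    _entity(g, "E3", 320.0, 190.0, "C")
    _edge(g, "e1", "E1", "P", production=False)
    _edge(g, "e2", "E2", "P", production=False)
    _edge(g, "e3", "P", "E3", production=True)
    out["irreversible_horizontal"] = g

    g = YedGraph()
    _process(g, "P", 200.0, 200.0)
    _entity(g, "E1", 150.0, 60.0, "A")
    _entity(g, "E2", 230.0, 60.0, "B")
    _entity(g, "E3", 180.0, 330.0, "C")
    _edge(g, "e1", "E1", "P", production=False)
    _edge(g, "e2", "E2", "P", production=False)
    _edge(g, "e3", "P", "E3", production=True)
    out["irreversible_vertical"] = g

    return out
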