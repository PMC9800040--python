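"""In-memory model of a yEd-flavoured GraphML document.

Restricted to the SBGN palette vocabulary: generic nodes whose
``configuration`` is one of the ``com.yworks.sbgn.*`` strings, group nodes
for compartments (and complexes), and polyline edges whose arrowheads encode
the PD arc classes.  The yEd palette has no native process ports, clone
markers or nested auxiliary units — those are exactly the gaps the two
converters bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .pd_model import ArcClass, BBox, GlyphClass, Point


class ClassificationError(ValueError):
    """A node/edge style that does not belong to the SBGN palette vocabulary."""


# ---------------------------------------------------------------------------
# Table of generic-node configuration strings (the yEd SBGN palette encodings)

CONFIG_COMPLEX = "com.yworks.sbgn.Complex"
CONFIG_MACROMOLECULE = "com.yworks.sbgn.Macromolecule"
CONFIG_NUCLEIC_ACID_FEATURE = "com.yworks.sbgn.NucleicAcidFeature"
CONFIG_SIMPLE_CHEMICAL = "com.yworks.sbgn.SimpleChemical"
CONFIG_UNSPECIFIED_ENTITY = "com.yworks.sbgn.UnspecifiedEntity"
CONFIG_PERTURBING_AGENT = "com.yworks.sbgn.PerturbingAgent"
CONFIG_PHENOTYPE = "com.yworks.sbgn.Phenotype"
CONFIG_EMPTY_SET = "com.yworks.sbgn.EmptySet"
CONFIG_PROCESS = "com.yworks.sbgn.Process"
CONFIG_OPERATOR = "com.yworks.sbgn.Operator"
CONFIG_SUBMAP = "com.yworks.sbgn.Submap"
CONFIG_TAG = "com.yworks.sbgn.Tag"
CONFIG_STATE_VARIABLE = "com.yworks.sbgn.StateVariable"
CONFIG_UNIT_OF_INFORMATION = "com.yworks.sbgn.UnitOfInformation"
CONFIG_GROUP = "y:GroupNode"

#: Style-property names used by the yEd SBGN palette.
ATTR_MCOUNT = "com.yworks.sbgn.style.mcount"
ATTR_INVERSE = "com.yworks.sbgn.style.inverse"
#: Converter-owned style properties (no native palette support).
ATTR_CLONE = "com.yworks.sbgn.style.cloneMarker"
ATTR_CLONE_LABEL = "com.yworks.sbgn.style.cloneLabel"
ATTR_FILL = "fill"
ATTR_STROKE = "stroke"

#: Label spellings that disambiguate the shared Process configuration.
LABEL_OMITTED = "\\\\"
LABEL_UNCERTAIN = "?"

_SIMPLE_CONFIGS: dict[str, GlyphClass] = {
    CONFIG_COMPLEX: GlyphClass.COMPLEX,
    CONFIG_MACROMOLECULE: GlyphClass.MACROMOLECULE,
    CONFIG_NUCLEIC_ACID_FEATURE: GlyphClass.NUCLEIC_ACID_FEATURE,
    CONFIG_SIMPLE_CHEMICAL: GlyphClass.SIMPLE_CHEMICAL,
    CONFIG_UNSPECIFIED_ENTITY: GlyphClass.UNSPECIFIED_ENTITY,
    CONFIG_PERTURBING_AGENT: GlyphClass.PERTURBING_AGENT,
    CONFIG_PHENOTYPE: GlyphClass.PHENOTYPE,
    CONFIG_EMPTY_SET: GlyphClass.SOURCE_AND_SINK,
    CONFIG_SUBMAP: GlyphClass.SUBMAP,
    CONFIG_STATE_VARIABLE: GlyphClass.STATE_VARIABLE,
    CONFIG_UNIT_OF_INFORMATION: GlyphClass.UNIT_OF_INFORMATION,
}

_OPERATOR_LABELS: dict[str, GlyphClass] = {
    "AND": GlyphClass.AND,
    "OR": GlyphClass.OR,
    "NOT": GlyphClass.NOT,
}


class ArrowType(str, Enum):
    """yFiles arrowhead tokens (the frozen dialect subset)."""

    NONE = "none"
    STANDARD = "standard"
    WHITE_DELTA = "white_delta"
    WHITE_DIAMOND = "white_diamond"
    T_SHAPE = "t_shape"
    CIRCLE = "circle"
    WHITE_DELTA_BAR = "white_delta_bar"


#: Bijection between (source_arrow, target_arrow) and PD arc class.
ARROWS_TO_ARC: dict[tuple[ArrowType, ArrowType], ArcClass] = {
    (ArrowType.NONE, ArrowType.NONE): ArcClass.CONSUMPTION,
    (ArrowType.NONE, ArrowType.STANDARD): ArcClass.PRODUCTION,
    (ArrowType.NONE, ArrowType.CIRCLE): ArcClass.CATALYSIS,
    (ArrowType.NONE, ArrowType.WHITE_DELTA): ArcClass.STIMULATION,
    (ArrowType.NONE, ArrowType.T_SHAPE): ArcClass.INHIBITION,
    (ArrowType.NONE, ArrowType.WHITE_DIAMOND): ArcClass.MODULATION,
    (ArrowType.NONE, ArrowType.WHITE_DELTA_BAR): ArcClass.NECESSARY_STIMULATION,
}

ARC_TO_ARROWS: dict[ArcClass, tuple[ArrowType, ArrowType]] = {
    v: k for k, v in ARROWS_TO_ARC.items()
}


@dataclass
class YedNodeStyle:
    configuration: str
    style_attrs: dict[str, str] = field(default_factory=dict)
    is_group: bool = False

    @property
    def mcount(self) -> Optional[int]:
        raw = self.style_attrs.get(ATTR_MCOUNT)
        return int(raw) if raw is not None else None

    @property
    def inverse(self) -> bool:
        return self.style_attrs.get(ATTR_INVERSE, "").lower() == "true"

    @property
    def clone(self) -> bool:
        return self.style_attrs.get(ATTR_CLONE, "").lower() == "true"


@dataclass
class YedNode:
    id: str
    geometry: BBox
    style: YedNodeStyle
    label: Optional[str] = None
    parent_group: Optional[str] = None
    aux_refs: list[str] = field(default_factory=list)


@dataclass
class YedEdgeStyle:
    source_arrow: ArrowType = ArrowType.NONE
    target_arrow: ArrowType = ArrowType.NONE
    colour: Optional[str] = None


@dataclass
class YedEdge:
    id: str
    source: str
    target: str
    style: YedEdgeStyle = field(default_factory=YedEdgeStyle)
    bends: list[Point] = field(default_factory=list)
    label: Optional[str] = None


@dataclass
class YedGraph:
    nodes: dict[str, YedNode] = field(default_factory=dict)
    edges: dict[str, YedEdge] = field(default_factory=dict)

    def add_node(self, node: YedNode) -> YedNode:
        self.nodes[node.id] = node
        return node

    def add_edge(self, edge: YedEdge) -> YedEdge:
        self.edges[edge.id] = edge
        return edge

    def children_of(self, group_id: str) -> list[YedNode]:
        return [n for n in self.nodes.values() if n.parent_group == group_id]


def node_class_of(style: YedNodeStyle, label: Optional[str] = None) -> GlyphClass:
    """Classify a yEd node style (plus disambiguating label) as a PD glyph class.

    The shared ``Process`` configuration is split by its label (double
    backslashes mean an omitted process, a question mark an uncertain one);
    operators read AND/OR/NOT from their label; everything else is a direct
    configuration-string lookup.
    """
    cfg = style.configuration
    if style.is_group and cfg == CONFIG_GROUP:
        return GlyphClass.COMPARTMENT
    if cfg == CONFIG_PROCESS:
        text = (label or "").strip()
        if text == LABEL_OMITTED:
            return GlyphClass.OMITTED_PROCESS
        if text == LABEL_UNCERTAIN:
            return GlyphClass.UNCERTAIN_PROCESS
        return GlyphClass.PROCESS
    if cfg == CONFIG_OPERATOR:
        kind = _OPERATOR_LABELS.get((label or "").strip().upper())
        if kind is None:
            raise ClassificationError(f"operator node with unrecognized label {label!r}")
        return kind
    if cfg == CONFIG_TAG:
        return GlyphClass.TAG
    try:
        return _SIMPLE_CONFIGS[cfg]
    except KeyError:
        raise ClassificationError(f"unrecognized node configuration {cfg!r}") from None


def edge_class_of(style: YedEdgeStyle) -> ArcClass:
    """Map an arrowhead pair to its PD arc class (a strict bijection)."""
    key = (style.source_arrow, style.target_arrow)
    try:
        return ARROWS_TO_ARC[key]
    except KeyError:
        raise ClassificationError(
            f"unrecognized arrow pattern source={style.source_arrow.value!r} "
            f"target={style.target_arrow.value!r}"
        ) from None
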