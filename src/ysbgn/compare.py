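"""Round-trip equivalence between two PD maps.

A PD → yEd → PD round trip cannot be the identity: yEd has no ports, so
port ids and exact port positions are reconstructed, and the bend points the
forward converter adds to visualise antennas are not recovered.  What must
survive is the biology: glyph classes, labels, compartment membership,
parent containment, clone flags, multimer cardinality, state-variable
values, process orientation, and the arc structure with endpoints compared
at the glyph level (ports collapsed onto their owning process).

:func:`roundtrip_differences` returns a human-readable list of everything
outside that equivalence; an empty list means the maps are equivalent.
"""

from __future__ import annotations

from collections import Counter

from .pd_model import Glyph, PDMap

_PRESERVED_FIELDS = (
    "cls",
    "label",
    "compartment_ref",
    "parent",
    "clone",
    "clone_label",
    "multimer_cardinality",
    "state",
    "orientation",
)


def _collapsed_arc_key(pd: PDMap, port_owner: dict[str, str], arc) -> tuple:
    src = port_owner.get(arc.source, arc.source)
    tgt = port_owner.get(arc.target, arc.target)
    return (arc.cls, src, tgt)


def roundtrip_differences(original: PDMap, converted: PDMap) -> list[str]:
    """Differences outside the documented round-trip equivalence relation."""
    diffs: list[str] = []
    if set(original.glyphs) != set(converted.glyphs):
        only_a = set(original.glyphs) - set(converted.glyphs)
        only_b = set(converted.glyphs) - set(original.glyphs)
        if only_a:
            diffs.append(f"glyphs missing after round trip: {sorted(only_a)[:5]}")
        if only_b:
            diffs.append(f"glyphs invented by round trip: {sorted(only_b)[:5]}")

    for gid in sorted(set(original.glyphs) & set(converted.glyphs)):
        a: Glyph = original.glyphs[gid]
        b: Glyph = converted.glyphs[gid]
        for name in _PRESERVED_FIELDS:
            va, vb = getattr(a, name), getattr(b, name)
            if va != vb:
                diffs.append(f"glyph {gid}: {name} {va!r} -> {vb!r}")
        if sorted(a.children) != sorted(b.children):
            diffs.append(f"glyph {gid}: children {sorted(a.children)} -> {sorted(b.children)}")
        ea = {k: v for k, v in a.extension.items() if k in ("fill", "stroke")}
        eb = {k: v for k, v in b.extension.items() if k in ("fill", "stroke")}
        if ea != eb:
            diffs.append(f"glyph {gid}: colours {ea} -> {eb}")

    owners_a = {p.id: p.owner for p in original.iter_ports()}
    owners_b = {p.id: p.owner for p in converted.iter_ports()}
    arcs_a = Counter(_collapsed_arc_key(original, owners_a, x) for x in original.arcs.values())
    arcs_b = Counter(_collapsed_arc_key(converted, owners_b, x) for x in converted.arcs.values())
    for key in (arcs_a - arcs_b):
        diffs.append(f"arc lost in round trip: {key}")
    for key in (arcs_b - arcs_a):
        diffs.append(f"arc invented by round trip: {key}")
    return diffs
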