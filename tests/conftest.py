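import pytest

from ysbgn.pd_model import Arc, ArcClass, BBox, Glyph, GlyphClass, Orientation, PDMap, Point, Port


def build_process_map(n_consumption: int = 2, n_production: int = 1) -> PDMap:
    """A hand-built map: one horizontal process with ports and flux arcs.

    Process box at (100, 100)-(120, 120); consumption entities on the left,
    production entities on the right, attached to the left/right ports.
    """
    pd = PDMap()
    proc = Glyph(
        id="P",
        cls=GlyphClass.PROCESS,
        bbox=BBox(100.0, 100.0, 20.0, 20.0),
        orientation=Orientation.HORIZONTAL,
    )
    proc.ports = [
        Port(id="P.1", position=Point(90.0, 110.0), owner="P"),
        Port(id="P.2", position=Point(130.0, 110.0), owner="P"),
    ]
    pd.add_glyph(proc)
    for k in range(n_consumption):
        ent = Glyph(
            id=f"C{k}",
            cls=GlyphClass.SIMPLE_CHEMICAL,
            bbox=BBox(10.0, 60.0 + 70.0 * k, 60.0, 40.0),
            label=f"sub{k}",
        )
        pd.add_glyph(ent)
        pd.add_arc(Arc(id=f"ac{k}", cls=ArcClass.CONSUMPTION, source=ent.id, target="P.1"))
    for k in range(n_production):
        ent = Glyph(
            id=f"R{k}",
            cls=GlyphClass.SIMPLE_CHEMICAL,
            bbox=BBox(180.0, 60.0 + 70.0 * k, 60.0, 40.0),
            label=f"prod{k}",
        )
        pd.add_glyph(ent)
        pd.add_arc(Arc(id=f"ap{k}", cls=ArcClass.PRODUCTION, source="P.2", target=ent.id))
    return pd


@pytest.fixture
def process_map() -> PDMap:
    return build_process_map()
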