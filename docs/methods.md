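# Methods

## The conversion model

`ysbgn` treats a map as two isomorphic-but-lossy views of the same biology:

- a **PDMap** — SBGN Process Description glyphs (entity pools, processes,
  operators, compartments, auxiliary units) and arcs (consumption,
  production, and the five modulation classes), with geometry in abstract
  canvas units, top-left origin, y growing downward;
- a **YedGraph** — yEd GraphML nodes (generic nodes carrying
  `com.yworks.sbgn.*` configuration strings, group nodes for containers)
  and polyline edges whose arrowhead pair encodes the arc class.

Both formats share the same coordinate convention, so conversion is
geometry-identity: node geometry equals glyph bbox exactly, bends pass
through unchanged. No layout is ever computed; that is the editor's job.

The information-losing direction is PD → yEd: yEd has no ports, no clone
marker, no association/dissociation shape, no up/down tag. The converter's
substance is the reconstruction of that information on the way back.

## Port reconstruction (yEd → SBGN)

Every SBGN process carries exactly two ports, subject to two validity
rules: (1) all arcs on one port have the same class, and (2) every port has
at least one arc. yEd edges attach to the process box, so the assignment is
inferred per process from its incident flux arcs (modulation-family arcs
attach to the body and are excluded throughout):

- **Classification.** Irreversible ⇔ at least one consumption *and* one
  production arc; reversible ⇔ all flux arcs are production. This is taken
  as the *definition* of reversibility, not a heuristic; no synthetic
  consumption arcs are ever created for reversible processes.
- **Arc position.** The bend adjacent to the process end if the edge has
  bends, else the far endpoint, taken as the far node's bbox center (the
  formats do not record an exact attachment point for node-attached edges).
  Its *side* is the axis of largest displacement from the process center;
  exact diagonal ties go to left/right (the horizontal bias).
- **Orientation.** Initially horizontal; flipped to vertical when
  top/bottom sides hold the strict majority of flux-arc positions. A flip
  recomputes the candidate port positions and re-runs the assignment once
  (logged as a notification).
- **Irreversible assignment.** Consumptions on one port, productions on the
  other. The physical side receiving consumption is the majority sign of
  the consumption positions along the orientation axis; ties put
  consumption on the left/top port.
- **Reversible assignment.** Each arc goes to the port with the smaller
  Euclidean distance from its arc position to the candidate port position
  (equidistant arcs go to port 1; arcs are processed in id order). If one
  port ends empty, the single arc farthest from the occupied port is moved
  to the empty one — at most one repair per process, which is the minimal
  change that restores rule (2). The distance is measured to each candidate
  *port position*, not to the glyph box; measuring to the box would leave
  the two-port assignment undefined.
- **Port placement.** Side midpoints offset outward by the antenna length
  (default 10 canvas units, `--antenna-length`). The same constant is used
  by the forward converter when a milestone-2 file legally omits port
  coordinates.
- **Direction normalization.** PD convention is consumption entity→port and
  production port→entity. Hand-drawn edges pointing the other way are
  flipped (bends reversed) with a warning, both at SBGN parse time and
  during port rewiring.

Degenerate drawings are handled without crashing and without emitting
invalid SBGN: a process with a single flux arc cannot satisfy rule (2) and
is emitted *without* ports plus an error record; an all-consumption process
gets the reversible-style nearest-port assignment over its consumption arcs
plus an error record (rule (1) still holds per port).

## Clone detection

Entity pools are grouped by (case-folded label, glyph class, compartment,
multimer cardinality, multiset of state-variable (value, variable) pairs);
every member of a group of size ≥ 2 receives a clone marker. The
compartment is part of the key by default — the same species in two
compartments is two distinct pools — switchable with
`--clone-policy global`. Unlabeled pools (e.g. empty sets) never match.
Nodes already carrying the forward converter's clone style attribute keep
their marker regardless.

## Auxiliary units

The forward converter emits state variables and units of information as
satellite nodes and records their ids in a converter-owned
`ysbgn.auxrefs` GraphML key on the parent node. The reverse converter
follows those references; for hand-drawn files lacking them it falls back
to geometry: the parent is the candidate node whose boundary band (bbox
expanded by 5 units) overlaps the unit most, ties broken by center distance
then id. State labels parse as `value@variable`, a bare label as value
only. Orphan units become standalone glyphs with a warning.

## Dialect choices

Encodings the source formats leave open are frozen in one place each
(`schema.py`, `graphml_io.py`, `yed_model.py`):

- SBGN-ML is written as milestone 2 (`http://sbgn.org/libsbgn/0.2`),
  glyphs before arcs; newer namespaces are read tolerantly. Emitted files
  are checked against a package-authored XSD of that structure.
- Colours/annotations ride in a converter-owned `<extension>` payload
  (`urn:ysbgn:dialect`) on the SBGN side and in `y:Fill`/`y:BorderStyle`
  plus `y:StyleProperties` on the yEd side; unknown extension children are
  preserved verbatim as opaque strings.
- Multimers are written with conventional `"<class> multimer"` class
  strings; the cardinality travels in the extension payload and in the
  `com.yworks.sbgn.style.mcount` style property.
- Clone markers use a converter-owned style property
  (`com.yworks.sbgn.style.cloneMarker`) — the yEd palette has no native
  one; detection covers files lacking it.
- Compartments are GraphML group nodes (`y:GroupNode`); complexes are
  *generic* group nodes carrying the Complex configuration so membership
  round-trips structurally.
- Arrowhead tokens (`standard`, `white_delta`, `white_diamond`, `t_shape`,
  `circle`, `white_delta_bar`, `none`) are yEd-version-dependent spellings;
  `yed_model.ArrowType` is the single place to adjust them.

## The synthetic-map generator

`fixtures.generate_pd` lays processes on a 420×360 grid with ±12-unit
uniform jitter; consumption entities sit on the port-1 side (left or top),
production entities on the port-2 side, 160–195 units out with ±8-unit
jitter, so every arc position has an unambiguous side — anchor ties occur
only in fixtures built explicitly for them. Irreversible processes get 1–3
consumption and 1–3 production arcs, reversible ones (default 30%) 2–4
production arcs split over both sides; 25% of processes gain a
body-attached modulation arc. Entity classes are drawn with
simple-chemical-heavy weights; labels recur with probability
`clone_fraction` (default 0.15) and duplicate groups are clone-marked with
the same key the detector uses; 20% of macromolecule-like pools carry an
auxiliary unit; 10% of eligible pools are multimers. `generate_yed` is the
forward conversion of the same map with ports stripped first, so the
reverse algorithms are genuinely exercised rather than replayed.
`random_process_graph` complements the grid with adversarial single-process
graphs: 1–8 flux edges at random angles, random class mix and drawing
direction, occasional bends — this is what drives the degenerate and repair
paths.

What the generator does *not* emulate: biologically meaningful
stoichiometry or naming, curved splines, edges whose nearest-bend anchor
contradicts the far-node side, overlapping/dense layouts where the
geometric aux-unit fallback could mis-attach. Passing tests therefore
demonstrate algorithmic correctness under clean geometry, not robustness to
arbitrarily messy hand drawings — for those, the conversion report is the
safety net.

The scale scenario (8 compartments, 3763 distinct species labels, 5535
processes, ≈ 32k glyphs / 22k arcs) emulates a genome-scale metabolic map;
both conversion directions complete in well under a second per direction on
one CPU, with the reverse direction consistently slower because of the
port/clone/aux reconstruction passes — the acceptance script reports both
timings and their ordering rather than asserting wall-clock values.

## Numerical and degenerate-input choices

- All tie-breaks are deterministic and seed-free: orientation tie →
  horizontal; equidistant arc → port 1; consumption-side tie → left/top;
  farthest-arc tie → higher arc id; aux-parent tie → smaller center
  distance, then lower id.
- Distance comparisons in the test oracles use a 1e-9 tolerance; the
  assignment itself compares exact floats (ties are legitimate and handled
  by the ordering rules above).
- An arc position coinciding with the process center defaults to the left
  side and is logged.
- Float serialization uses `repr`, which round-trips IEEE doubles exactly;
  both I/O layers are tested as read∘write = identity.

## Known limitations

- Association/dissociation and up/down tags are not recoverable after a
  round trip (degraded by design, with logged records).
- Submaps are opaque nodes; their internal maps are out of scope, as are
  the SBGN AF/ER languages.
- Arc-level extension payloads other than the stroke colour are not carried
  into GraphML.
- yEd's compressed `.graphmlz` container is not read or written.
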