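# ysbgn

Bidirectional converter between **SBGN-ML Process Description** (the XML
exchange format of the Systems Biology Graphical Notation) and
**yEd-flavoured GraphML** (the dialect written by the yEd graph editor with
its yFiles extensions and SBGN palette).

Systems biologists draw large metabolic maps — thousands of entity pools and
reactions — and need both a comfortable editor and a standard storage
format. yEd is an excellent general-purpose editor with an SBGN palette, but
it does not speak SBGN-ML; SBGN tools speak SBGN-ML but struggle at scale.
`ysbgn` bridges the two: draw in yEd, store in SBGN, and go back again.

## What the converter actually computes

Most glyphs translate one-to-one (macromolecule ↔
`com.yworks.sbgn.Macromolecule`, compartment ↔ yEd group node, multimer ↔
the `mcount` style attribute, and so on), but three things have no direct
counterpart and are reconstructed algorithmically:

**Process ports.** An SBGN process is a square box with two antenna tips
("ports") that separate the two sides of the reaction equation; yEd attaches
edges straight to the box. Going to yEd, each flux arc gains a bend point at
its port position so the antennas stay visible. Coming back, ports must be
*inferred*:

1. a process is **irreversible** if it has both consumption and production
   arcs — consumptions go to one port, productions to the other, with the
   physical side chosen by majority vote of the consumption arc positions;
2. a process is **reversible** if all its flux arcs are production arcs —
   each arc is assigned to the port nearest to its *arc position* (the edge
   endpoint, or the bend adjacent to the process) by Euclidean distance, and
   if one port ends up empty the single farthest arc is moved onto it so
   that every port is connected to at least one arc;
3. **orientation** starts horizontal and flips to vertical when most arc
   positions sit above/below the box, re-running the assignment once with
   top/bottom ports.

Modulation arcs (catalysis, stimulation, inhibition, modulation, necessary
stimulation) attach to the process body and never occupy ports.

**Clone markers.** Ubiquitous species (ATP, H₂O, …) are drawn many times;
SBGN marks the copies. The reverse converter detects clones as entity pools
sharing label, class, compartment, multimer cardinality and state-variable
decoration, in groups of two or more.

**Auxiliary units.** State variables and units of information are nested
child glyphs in SBGN but free-standing nodes in yEd, linked by identifier
(or, in hand-drawn files, by sitting on their parent's border). The reverse
converter re-attaches them, parsing `value@variable` state labels.

Association/dissociation processes and up/down-oriented tags have no yEd
shape; they are degraded (to generic processes and left tags) and every
degradation is logged in a structured conversion report. A broken element
never aborts a file — errors are collected per element.

## Worked example

```python
from ysbgn.fixtures import FixtureSpec, generate_yed
from ysbgn import yed_to_sbgn
from ysbgn.pd_model import validate, PROCESS_CLASSES

graph = generate_yed(FixtureSpec(n_compartments=2, n_pools=12, n_processes=6, seed=11))
pd, report = yed_to_sbgn.convert(graph)
print(f"nodes in: {len(graph.nodes)}  edges in: {len(graph.edges)}")
print(f"glyphs out: {len(pd.glyphs)}  arcs out: {len(pd.arcs)}")
print(f"violations: {len(validate(pd))}  report: {report.summary()}")
```

prints

```
nodes in: 30  edges in: 20
glyphs out: 30  arcs out: 20
violations: 0  report: {'notifications': 1, 'warnings': 0, 'errors': 0}
```

Thirty yEd nodes (two compartment groups, six port-less process boxes, the
entity pools and their auxiliary units) come back as thirty glyphs; every
process now carries two connected ports, two recurring pools got clone
markers, and the map passes all PD validity rules — the one notification is
an orientation flip on a vertically drawn process.

From the shell:

```
ysbgn fixtures --out demo --seed 5                 # synthetic .sbgn/.graphml pair
ysbgn convert demo/fixture_seed5.graphml -o back.sbgn --report rep.jsonl
ysbgn convert maps/ --bulk -o out/ --jobs 4        # whole-directory conversion
```

Exit status is 0 for a clean run, 1 if warnings were logged (e.g. an output
file was overwritten), 2 on errors; in bulk mode one bad file is reported
and the rest of the batch still converts.

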