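# Methods

## Provenance model

provlink describes an experiment with eight kinds of components — data
(datasets and their images), agents, activities, plans, steps, settings,
instruments and materials — and treats the experiment itself as a plan.
Computational work enters through notebooks: a notebook is a plan too, its
code cells are steps, and each recorded run of a cell is an activity linked
to its step. Linking a notebook to an experiment adds a single sub-plan
triple, after which one SPARQL query can traverse from a scientist's role
through an instrument setting to the run time of the notebook cell that
produced a figure.

The vocabulary is deliberately closed: the toolkit emits only the classes
and properties pinned in `provlink/vocab.py` (a subset of PROV-O, P-Plan
and the REPRODUCE-ME extension). Emitting any other term raises
immediately, and a test scans generated graphs for drift. The `repr:`
namespace IRI is pinned in that one module so the term set can be
re-aligned to a published ontology revision without touching the mapping
code. Both competency queries are expressible in this subset by
construction.

## Capture

Execution records live under one well-known key in the cell metadata
(`provenance`, with a `schema` version field), so documents with captured
history remain valid nbformat-4 notebooks. A record stores start and end
time (ISO-8601 UTC, millisecond precision — lexicographic order equals
temporal order), the elapsed time as an exact integer `end − start` in
milliseconds, snapshots of the source and outputs, a content-derived
environment reference, and a `sequence_index` assigned at append time so
that `(start_time, sequence_index)` is unique even when two runs share a
start timestamp. Records only ever append; earlier records are immutable,
which makes history monotone — and makes documents grow with every run, a
cost accepted by design (an optional output-size cap could bound it, but
the default keeps full snapshots).

Only code cells execute, so only code cells carry provenance; markdown and
raw cells never do. Elapsed time is stored numerically and humanized only
for display (`41.3ms`, `2.5s`, `2 min 35s`, `1 h 0 min 0s`; sub-second in
milliseconds, sub-minute in tenths of seconds, larger values in
minute/second then hour/minute/second form with seconds rounded).

Execution is pluggable. The default test executor is a pure, table-driven
mock (same source, same outputs; unknown sources become error outputs, as
a notebook would show them, without aborting the remaining cells). A
seeded hash-based mock serves the CLI's dry runs, and a headless
in-process Python executor (`exec` in one shared namespace, capturing
stdout, a trailing expression's repr, and exceptions) covers real
whole-notebook runs. No kernel process or network is ever required.

## Diffing

Two executions of a cell are selected by start time (sequence index
disambiguates ties). Sources are diffed line-by-line with a classic LCS
dynamic program; the edit script is minimal, reconstructs either side
exactly, and uses a content-based tie-break between equally cheap scripts
that is self-dual, so `diff(a, b)` and `diff(b, a)` are exact mirrors.
Intra-line refinement is out of scope — the presentation is line-marked.
Outputs are paired positionally within their content kind (text, image,
error, other): an output with no partner is reported as added/removed, so
a text output replaced by an image appears as one removal plus one
addition. Image payloads are compared by decoded-byte equality only; no
perceptual metric is attempted, and a changed image renders as a one-line
indicator with byte sizes.

## RDF mapping and round trips

Individuals get IRIs of the form
`base + {notebook|cell|execution|variable|setting|…}/<stable id>`, where
stable ids are UUIDs persisted in the document, so export → import →
export is the identity on the triple set. No blank nodes are ever emitted
(they would break round-trip stability). Execution snapshots are attached
to the activity node as one JSON literal under `rdf:value` rather than as
distinct `prov:Entity` nodes — the alternative was considered and
rejected to keep the graph within the closed vocabulary and the reverse
mapping simple. Environment attributes become per-attribute setting nodes
(`repr:hasSetting` → `repr:name`/`rdf:value`), package versions under
`package:<name>` keys. `repr:executionTime` is an `xsd:integer` in
milliseconds: an `xsd:duration` literal would defeat SPARQL arithmetic in
practice, and the humanized form is display-only. Setting units are folded
into the value literal ("488 nm") because the closed vocabulary carries no
unit property.

Markdown and raw cells do not execute and are not steps; they are
preserved as opaque entities carrying their document position, so the
reverse mapping can interleave them correctly between the code cells
(whose order comes from the `isPrecededBy` chain, validated to be a total
order). Input/output variables additionally state
`p-plan:isVariableOfPlan` toward the notebook so plan-scoped query
patterns can reach notebook content once a notebook is attached to an
experiment.

Round-trip equality is defined under a single documented normalization
(`provlink.rdf.normalize`): `execution_count`, non-provenance cell
metadata, non-provenance notebook metadata and unknown top-level document
keys are declared non-semantic; everything else — cell order and types,
sources, latest outputs, all execution records, stable ids, environment —
round-trips exactly.

Turtle serialization is canonical: a sorted prefix block, then one triple
per line sorted by subject, predicate, object, with JSON-escaped literal
lexicals. Equal graphs are byte-equal documents, which turns graph
comparison into string comparison in tests and makes exports diffable.
Note that rdflib normalizes `xsd:dateTime` lexicals at literal creation
(`…T00:00:00.000Z` → `…T00:00:00+00:00`); the canonical form is therefore
the XSD-normalized one.

## Experiment store and versioning

The store is a single JSON document (experiments, linked notebook
documents, version history) — portable and diffable; no relational schema
is involved. Every mutation auto-saves a full snapshot as a new version
with strictly increasing save times (a stalled clock is nudged forward by
1 ms), so history length equals mutation count by construction and any two
versions can be compared field-by-field (dotted/indexed change paths with
old/new values). Agent roles are descriptive metadata; no permission model
is enforced. Manual lab activities are representable as steps without
corresponding activities — only notebook executions have captured timing.
Step predecessor chains are validated acyclic and within one plan.

## Queries and the ProvTrack view

SPARQL evaluation is delegated to rdflib's SPARQL 1.1 engine; the
supported floor is basic graph patterns, OPTIONAL, UNION, DISTINCT and
FILTER (SERVICE, named graphs, MINUS and aggregation are rejected
explicitly). The toolkit's own contribution is graph construction, the two
verbatim path queries, the query-splitting strategy and the test oracles.
Both path queries are run with the experiment or notebook pre-bound, and
missing components yield fewer (possibly zero) rows rather than errors —
the expected behaviour for incomplete metadata.

The ProvTrack view is assembled from one small SELECT per relation family
(attribution, datasets/members, parts, settings, sub-plans, steps,
variables, executions, references) instead of one monolithic path query;
their union reconstructs the full tree. Tree parents are assigned by a
fixed relation priority during breadth-first assembly, so the view is
deterministic; cross links (image↔instrument, step order, inverse
properties) are carried as extra edges. Node types are reduced to six
(Entity, Agent, Activity, Step, Plan, Variable) with the most specific
type winning — an experiment node, typed both `repr:Experiment` and
`p-plan:Plan`, renders as a Plan. Infobox properties are the node's
literal-valued triples, sorted by predicate name for determinism. Search
is case-insensitive substring over node labels or edge property names, in
document order.

## Synthetic data

The generators define the study conditions for every test. Notebooks:
`n_cells` code cells (default 3) with 2 runs each, outputs drawn 60/20/20
from text, tiny deterministic PNGs and synthetic errors; the mock clock
starts at 2020-01-01T00:00:00Z, cell starts are one second apart and each
run lasts 500 ms, so humanized times are stable strings. Experiments
follow profiles shaped after the kinds of studies the model targets —
`cpcf` (confocal patch-clamp fluorometry), `palm_dstorm` (localization
microscopy) and `screen` (an imaging screen, the richest profile: it
touches every vocabulary term, which a coverage test enforces); `minimal`
is the degenerate empty description. Instrument/part/setting names and
materials are drawn from small realistic microscopy vocabularies.

What the generators do *not* emulate: real kernel timing jitter,
large/heterogeneous outputs, concurrent editing, malformed documents
beyond the cases tested, or the statistics of real metadata entry
(missingness here is all-or-nothing per profile). Passing tests
demonstrate the contracts — round-trip identity, monotone capture,
minimal diffs, query/oracle agreement, view completeness — not
performance or robustness on arbitrary real-world notebooks.

## Problem sizes and numerical choices

The randomized suites run at desk scale, chosen to finish in minutes on
one CPU: 200 seeded notebooks for the round-trip sweep, 30 graphs for
canonicalization, all source pairs up to 3 lines over a 3-symbol line
alphabet (1,681 pairs, exhaustive) plus 500 seeded random pairs up to 8
lines for the diff oracle, and 50 seeded stores (≤ 5 cells, ≤ 3 runs,
≤ 4 steps) for the competency-query oracles. Timestamps are truncated
(not rounded) to whole milliseconds on entry; duration formatting rounds
seconds as documented above; ties between equally minimal edit scripts
are broken by line content as described.

## Known limitations

- The reverse mapping restores the normalized notebook, not every byte of
  arbitrary third-party metadata (the normalization list above is the
  contract).
- Output pairing in diffs is positional within kind; a reordered pair of
  same-kind outputs reads as two modifications, not a move.
- Cross-notebook comparison pairs cells by stable id with positional
  fallback; notebooks never touched by provlink have no stable ids until
  first processed.
- The SPARQL feature floor excludes aggregation; row counting happens in
  the caller.
- The in-process Python executor shares one namespace across cells (as a
  notebook does) but provides no isolation or timeout.
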