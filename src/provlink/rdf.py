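"""RDF representation of notebook provenance and its turtle round trip.

A notebook with captured provenance maps onto the pinned PROV-O / P-Plan /
REPRODUCE-ME vocabulary as follows:

1. the notebook is a node typed ``repr:Notebook`` and ``p-plan:Plan``;
2. each code cell is a ``p-plan:Step`` with ``p-plan:isStepOfPlan`` the
   notebook;
3. consecutive code cells are chained by ``p-plan:isPrecededBy``
   (step *i* isPrecededBy step *i−1*);
4. each step carries one input variable (the cell's current source, linked
   by ``p-plan:hasInputVar`` and the inverse ``p-plan:isInputVarOf``, its
   content under ``rdf:value`` and a label under ``repr:name``) and one
   output variable (the latest outputs, via ``hasOutputVar`` /
   ``isOutputVarOf``); variables also state ``p-plan:isVariableOfPlan`` so
   plan-scoped queries can reach them;
5. each execution record is a ``prov:Activity`` with
   ``p-plan:correspondsToStep`` its step, ``prov:startedAtTime`` /
   ``prov:endedAtTime`` timestamps, the elapsed duration in integer
   milliseconds under ``repr:executionTime``, and its full snapshot
   (source, outputs, environment reference) as a JSON literal under
   ``rdf:value``;
6. execution-environment attributes attach to the notebook node as setting
   nodes (``repr:hasSetting`` → ``repr:name`` key / ``rdf:value`` value),
   one per attribute, with package versions under ``package:<name>`` keys.

Markdown and raw cells do not execute and are not steps; they are preserved
as opaque ordering entities (``repr:hasPart`` with a JSON payload carrying
their document position) so the reverse mapping can restore document order.

Individual IRIs are minted as ``base + {notebook|cell|execution|variable|
setting}/<stable id>``, so export → import → export is the identity on the
triple set.  No blank nodes are ever emitted.  Serialization is canonical:
sorted prefix block, then triples sorted by subject, predicate, object —
equal graphs yield byte-equal documents.
"""

from __future__ import annotations

import json
from urllib.parse import quote, unquote

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD
from rdflib.term import BNode

from .errors import BrokenChain, NotAProvlinkGraph, TurtleSyntaxError
from .notebook import (
    Cell,
    CellOutput,
    ExecutionEnvironment,
    ExecutionRecord,
    Notebook,
    ensure_stable_ids,
    format_timestamp,
    parse_timestamp,
)
from .vocab import CLASSES, PPLAN, PREFIXES, PROPERTIES, PROV, REPR

DEFAULT_BASE = "https://provlink.example.org/"


class ProvGraphDoc:
    """A set of triples over the closed vocabulary, turtle-serializable.

    Thin wrapper over an :class:`rdflib.Graph` that enforces the toolkit's
    invariants: set semantics, no blank nodes, and every predicate (and
    every ``rdf:type`` object) drawn from the term table.
    """

    def __init__(self, graph: Graph | None = None):
        self.graph = graph if graph is not None else Graph()
        for prefix, ns in PREFIXES.items():
            self.graph.bind(prefix, ns, replace=True)

    def add(self, subject: URIRef, predicate: URIRef, obj) -> None:
        if isinstance(subject, BNode) or isinstance(obj, BNode):
            raise ValueError("blank nodes are not allowed in provlink graphs")
        if predicate not in PROPERTIES:
            raise ValueError(f"predicate outside the closed vocabulary: {predicate}")
        if predicate == RDF.type and obj not in CLASSES:
            raise ValueError(f"class outside the closed vocabulary: {obj}")
        self.graph.add((subject, predicate, obj))

    def triples(self) -> set:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProvGraphDoc) and self.triples() == other.triples()

    def __hash__(self):  # pragma: no cover - identity hashing only
        return id(self)

    def objects(self, subject, predicate):
        return list(self.graph.objects(subject, predicate))

    def subjects(self, predicate, obj):
        return list(self.graph.subjects(predicate, obj))

    def union(self, other: "ProvGraphDoc") -> "ProvGraphDoc":
        merged = ProvGraphDoc()
        for t in self.graph:
            merged.graph.add(t)
        for t in other.graph:
            merged.graph.add(t)
        return merged


# --------------------------------------------------------------------------
# IRI minting

def mint(base: str, kind: str, *parts: str) -> URIRef:
    base = base if base.endswith(("/", "#")) else base + "/"
    path = "/".join(quote(str(p), safe="") for p in parts)
    return URIRef(f"{base}{kind}/{path}")


def iri_leaf(iri: URIRef) -> str:
    return unquote(str(iri).rsplit("/", 1)[-1])


# --------------------------------------------------------------------------
# notebook -> graph

def _env_settings(env: ExecutionEnvironment) -> list[tuple[str, str]]:
    pairs = [
        ("os_name", env.os_name),
        ("os_version", env.os_version),
        ("language_name", env.language_name),
        ("language_version", env.language_version),
        ("captured_at", format_timestamp(env.captured_at)),
    ]
    pairs.extend((f"package:{name}", version) for name, version in sorted(env.packages.items()))
    return pairs


def notebook_to_rdf(nb: Notebook, base: str = DEFAULT_BASE) -> ProvGraphDoc:
    """Materialize a notebook's provenance as an RDF graph.

    Stable identifiers are minted in place when absent so the export is
    reproducible thereafter.
    """
    ensure_stable_ids(nb)
    g = ProvGraphDoc()
    nbnode = mint(base, "notebook", nb.stable_id)
    g.add(nbnode, RDF.type, REPR.Notebook)
    g.add(nbnode, RDF.type, PPLAN.Plan)

    if nb.environment is not None:
        for key, value in _env_settings(nb.environment):
            setting = mint(base, "setting", nb.stable_id, key)
            g.add(nbnode, REPR.hasSetting, setting)
            g.add(setting, RDF.type, PROV.Entity)
            g.add(setting, REPR.name, Literal(key))
            g.add(setting, RDF.value, Literal(value))

    prev_step = None
    code_pos = 0
    for position, cell in enumerate(nb.cells):
        if cell.cell_type != "code":
            part = mint(base, "cell", cell.stable_id)
            payload = {"position": position, "cell_type": cell.cell_type, "source": cell.source}
            g.add(nbnode, REPR.hasPart, part)
            g.add(part, RDF.type, PROV.Entity)
            g.add(part, RDF.value, Literal(json.dumps(payload, sort_keys=True)))
            continue
        code_pos += 1
        step = mint(base, "cell", cell.stable_id)
        g.add(step, RDF.type, PPLAN.Step)
        g.add(step, PPLAN.isStepOfPlan, nbnode)
        g.add(step, REPR.name, Literal(f"cell {code_pos}"))
        if prev_step is not None:
            g.add(step, PPLAN.isPrecededBy, prev_step)
        prev_step = step

        invar = mint(base, "variable", cell.stable_id, "in")
        g.add(invar, RDF.type, PPLAN.Variable)
        g.add(step, PPLAN.hasInputVar, invar)
        g.add(invar, PPLAN.isInputVarOf, step)
        g.add(invar, PPLAN.isVariableOfPlan, nbnode)
        g.add(invar, RDF.value, Literal(cell.source))
        g.add(invar, REPR.name, Literal(f"input of cell {code_pos}"))

        outvar = mint(base, "variable", cell.stable_id, "out")
        g.add(outvar, RDF.type, PPLAN.Variable)
        g.add(step, PPLAN.hasOutputVar, outvar)
        g.add(outvar, PPLAN.isOutputVarOf, step)
        g.add(outvar, PPLAN.isVariableOfPlan, nbnode)
        g.add(outvar, RDF.value, Literal(json.dumps([o.to_nb_json() for o in cell.outputs], sort_keys=True)))
        g.add(outvar, REPR.name, Literal(f"output of cell {code_pos}"))

        for record in cell.executions:
            start_ms = format_timestamp(record.start_time)
            activity = mint(base, "execution", cell.stable_id, f"{start_ms}-{record.sequence_index}")
            g.add(activity, RDF.type, PROV.Activity)
            g.add(activity, PPLAN.correspondsToStep, step)
            g.add(activity, PROV.startedAtTime, Literal(start_ms, datatype=XSD.dateTime))
            g.add(activity, PROV.endedAtTime, Literal(format_timestamp(record.end_time), datatype=XSD.dateTime))
            g.add(activity, REPR.executionTime, Literal(record.elapsed_ms, datatype=XSD.integer))
            snapshot = {
                "source": record.source_snapshot,
                "outputs": [o.to_nb_json() for o in record.outputs_snapshot],
                "environment_ref": record.environment_ref,
                "sequence_index": record.sequence_index,
            }
            g.add(activity, RDF.value, Literal(json.dumps(snapshot, sort_keys=True)))
    return g


# --------------------------------------------------------------------------
# graph -> notebook  (the reproducibility service)

def normalize(nb: Notebook) -> Notebook:
    """The notebook restricted to its semantic content.

    The RDF mapping covers provenance, not every notebook nicety; the
    round-trip equality contract therefore excludes, in one documented
    place: ``execution_count``, non-provenance cell metadata, non-provenance
    notebook metadata, and unknown top-level document keys.  Everything else
    — cell order and types, sources, latest outputs, all execution records,
    stable identifiers, and the environment stamp — is preserved exactly.
    """
    return Notebook(
        notebook_metadata={},
        cells=[
            Cell(
                cell_type=c.cell_type,
                source=c.source,
                cell_metadata={},
                outputs=list(c.outputs) if c.cell_type == "code" else [],
                execution_count=None,
                stable_id=c.stable_id,
                executions=list(c.executions),
            )
            for c in nb.cells
        ],
        stable_id=nb.stable_id,
        environment=nb.environment,
    )


def _step_chain(g: ProvGraphDoc, nbnode: URIRef) -> list[URIRef]:
    steps = set(g.subjects(PPLAN.isStepOfPlan, nbnode))
    if not steps:
        return []
    pred: dict[URIRef, URIRef] = {}
    for step in steps:
        prevs = [p for p in g.objects(step, PPLAN.isPrecededBy) if p in steps]
        if len(prevs) > 1:
            raise BrokenChain(f"step {step} has {len(prevs)} predecessors")
        if prevs:
            pred[step] = prevs[0]
    roots = [s for s in steps if s not in pred]
    if len(roots) != 1:
        raise BrokenChain(f"expected exactly one chain root, found {len(roots)}")
    successors: dict[URIRef, URIRef] = {}
    for step, prev in pred.items():
        if prev in successors:
            raise BrokenChain(f"step {prev} has multiple successors")
        successors[prev] = step
    chain = [roots[0]]
    while chain[-1] in successors:
        chain.append(successors[chain[-1]])
    if len(chain) != len(steps):
        raise BrokenChain("isPrecededBy does not order all steps")
    return chain


def _one_literal(g: ProvGraphDoc, subject, predicate, what: str) -> str:
    values = g.objects(subject, predicate)
    if len(values) != 1:
        raise NotAProvlinkGraph(f"expected exactly one {what} on {subject}, found {len(values)}")
    return str(values[0])


def rdf_to_notebook(g: ProvGraphDoc) -> Notebook:
    """Reconstruct a notebook from a graph produced by :func:`notebook_to_rdf`."""
    nbnodes = sorted(set(g.subjects(RDF.type, REPR.Notebook)))
    if len(nbnodes) != 1:
        raise NotAProvlinkGraph(f"expected exactly one repr:Notebook node, found {len(nbnodes)}")
    nbnode = nbnodes[0]

    environment = _reconstruct_environment(g, nbnode)

    code_cells = []
    for step in _step_chain(g, nbnode):
        invars = [v for v in g.objects(step, PPLAN.hasInputVar)]
        outvars = [v for v in g.objects(step, PPLAN.hasOutputVar)]
        if len(invars) != 1 or len(outvars) != 1:
            raise NotAProvlinkGraph(f"step {step} must have exactly one input and one output variable")
        source = _one_literal(g, invars[0], RDF.value, "input value")
        outputs = [CellOutput.from_nb_json(o) for o in json.loads(_one_literal(g, outvars[0], RDF.value, "output value"))]
        executions = []
        for activity in g.subjects(PPLAN.correspondsToStep, step):
            snapshot = json.loads(_one_literal(g, activity, RDF.value, "execution snapshot"))
            executions.append(
                ExecutionRecord(
                    start_time=parse_timestamp(_one_literal(g, activity, PROV.startedAtTime, "start time")),
                    end_time=parse_timestamp(_one_literal(g, activity, PROV.endedAtTime, "end time")),
                    elapsed_ms=int(_one_literal(g, activity, REPR.executionTime, "execution time")),
                    source_snapshot=snapshot["source"],
                    outputs_snapshot=[CellOutput.from_nb_json(o) for o in snapshot["outputs"]],
                    environment_ref=snapshot.get("environment_ref"),
                    sequence_index=int(snapshot.get("sequence_index", 0)),
                )
            )
        code_cells.append(
            Cell(
                cell_type="code",
                source=source,
                outputs=outputs,
                stable_id=iri_leaf(step),
                executions=executions,
            )
        )

    other_cells = []
    for part in g.objects(nbnode, REPR.hasPart):
        payload = json.loads(_one_literal(g, part, RDF.value, "cell payload"))
        other_cells.append(
            (payload["position"], Cell(cell_type=payload["cell_type"], source=payload["source"], stable_id=iri_leaf(part)))
        )
    other_cells.sort(key=lambda pc: pc[0])

    # interleave: markdown/raw cells at their recorded positions, code cells
    # in chain order filling the remaining slots
    total = len(code_cells) + len(other_cells)
    cells: list[Cell | None] = [None] * total
    for position, cell in other_cells:
        if not (0 <= position < total) or cells[position] is not None:
            raise NotAProvlinkGraph(f"invalid document position {position}")
        cells[position] = cell
    it = iter(code_cells)
    cells = [c if c is not None else next(it) for c in cells]

    return Notebook(
        cells=cells,
        stable_id=iri_leaf(nbnode),
        environment=environment,
    )


def _reconstruct_environment(g: ProvGraphDoc, nbnode: URIRef) -> ExecutionEnvironment | None:
    attrs: dict[str, str] = {}
    for setting in g.objects(nbnode, REPR.hasSetting):
        key = _one_literal(g, setting, REPR.name, "setting key")
        attrs[key] = _one_literal(g, setting, RDF.value, "setting value")
    if not attrs:
        return None
    packages = {k.split(":", 1)[1]: v for k, v in attrs.items() if k.startswith("package:")}
    return ExecutionEnvironment(
        os_name=attrs.get("os_name", ""),
        os_version=attrs.get("os_version", ""),
        language_name=attrs.get("language_name", ""),
        language_version=attrs.get("language_version", ""),
        packages=packages,
        captured_at=parse_timestamp(attrs["captured_at"]) if "captured_at" in attrs else parse_timestamp("1970-01-01T00:00:00.000Z"),
    )


# --------------------------------------------------------------------------
# canonical turtle

def _term_text(term) -> str:
    if isinstance(term, URIRef):
        text = str(term)
        for prefix, ns in sorted(PREFIXES.items(), key=lambda kv: -len(str(kv[1]))):
            nstext = str(ns)
            if text.startswith(nstext):
                local = text[len(nstext):]
                if local and all(ch.isalnum() or ch in "_-." for ch in local) and not local.startswith((".", "-")) and not local.endswith("."):
                    return f"{prefix}:{local}"
        return f"<{text}>"
    if isinstance(term, Literal):
        lexical = json.dumps(str(term), ensure_ascii=True)
        if term.language:
            return f"{lexical}@{term.language}"
        if term.datatype and term.datatype != XSD.string:
            return f"{lexical}^^{_term_text(URIRef(term.datatype))}"
        return lexical
    raise ValueError(f"cannot serialize term {term!r}")


def serialize_turtle(g: ProvGraphDoc) -> str:
    """Canonical turtle: sorted prefixes, one sorted triple per line.

    Equal graphs serialize to byte-equal documents; an empty graph yields a
    document containing only the prefix declarations.
    """
    lines = [f"@prefix {prefix}: <{ns}> ." for prefix, ns in sorted(PREFIXES.items())]
    lines.append("")
    body = sorted(
        f"{_term_text(s)} {_term_text(p)} {_term_text(o)} ." for s, p, o in g.triples()
    )
    lines.extend(body)
    return "\n".join(lines) + "\n"


def parse_turtle(text: str) -> ProvGraphDoc:
    graph = Graph()
    try:
        graph.parse(data=text, format="turtle")
    except Exception as exc:
        raise TurtleSyntaxError(f"cannot parse turtle: {exc}") from exc
    for s, _, o in graph:
        if isinstance(s, BNode) or isinstance(o, BNode):
            raise TurtleSyntaxError("blank nodes are not supported in provlink graphs")
    return ProvGraphDoc(graph)
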