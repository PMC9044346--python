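"""Competency queries and the ProvTrack provenance-backtracking view.

The two printed competency questions run verbatim over materialized graphs:

* the complete path taken by a scientist for an experiment — agents and
  their roles, datasets and their images, instruments with parts and
  settings, sub-plans and their variables, steps with their input/output
  variables (an input/output UNION with OPTIONAL names, availability URLs
  and literature references);
* the complete path for a computational notebook experiment — steps, their
  executions with run times, input and output variables, and the order of
  steps.

SPARQL evaluation is delegated to rdflib's SPARQL 1.1 engine; supported
query features are basic graph patterns, OPTIONAL, UNION, DISTINCT and
FILTER.  The ProvTrack view is assembled from several smaller SELECTs (one
per component family) whose union reconstructs the full path — large
monolithic path queries are exactly what the splitting strategy avoids.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from rdflib import Literal, URIRef
from rdflib.namespace import RDF
from rdflib.plugins.sparql import prepareQuery

from .errors import QuerySyntaxError, UnknownNode, UnsupportedFeature
from .experiment import ExperimentStore
from .rdf import ProvGraphDoc, iri_leaf, mint, notebook_to_rdf
from .vocab import PPLAN, PREFIXES, PROV, REPR

_PREFIX_HEADER = "\n".join(f"PREFIX {p}: <{ns}>" for p, ns in sorted(PREFIXES.items()))

#: What is the complete path taken by a scientist for an experiment?
LISTING_1 = """\
SELECT DISTINCT * WHERE
{
  ?experiment a repr:Experiment ;
      prov:wasAttributedTo ?agent ; repr:hasDataset ?dataset ;
      prov:generatedAtTime ?generatedAtTime .
  ?agent repr:hasRole ?role .
  ?dataset prov:hadMember ?image .
  ?instrument p-plan:correspondsToVariable ?image ;
      repr:hasPart ?instrument_part .
  ?instrument_part repr:hasSetting ?setting .
  ?plan p-plan:isSubPlanOfPlan ?experiment .
  ?variable p-plan:isVariableOfPlan ?plan .
  ?step p-plan:isStepOfPlan ?experiment .
  OPTIONAL { ?step p-plan:isPrecededBy ?previousStep } .
  {
    ?Input p-plan:isInputVarOf ?step ; rdf:type ?InputType .
    OPTIONAL { ?Input repr:name ?InputName } .
  }
  UNION {
    ?Output p-plan:isOutputVarOf ?step ;
        rdf:type ?OutputType .
    OPTIONAL { ?Output repr:name ?OutputName } .
    OPTIONAL { ?Output repr:isAvailableAt ?outputUrl } .
    OPTIONAL { ?Output repr:reference ?OutputReference .
        ?OutputReference rdf:value ?OutputReferenceValue
    }
  }
}
"""

#: Complete path for a computational notebook experiment.
LISTING_2 = """\
SELECT DISTINCT * WHERE
{
  ?step p-plan:isStepOfPlan ?notebook .
  ?notebook a repr:Notebook .
  ?execution p-plan:correspondsToStep ?step ;
      repr:executionTime ?executionTime .
  ?step p-plan:hasInputVar ?inputVar ;
      p-plan:hasOutputVar ?outputVar ;
      p-plan:isPrecededBy ?previousStep .
}
"""

_DENIED_ALGEBRA = {
    "ServiceGraphPattern",
    "GraphGraphPattern",
    "Minus",
    "Group",
    "AggregateJoin",
    "GroupGraphPatternSub",  # never reached post-translation; kept for safety
}
_DENIED_NAMES = {"Service", "Graph", "Minus", "Group", "AggregateJoin"}


@dataclass
class ResultTable:
    """SPARQL SELECT results: ordered variables, deduplicated rows.

    Cell values are plain strings (full IRIs, literal lexical forms) or
    ``None`` for variables left unbound by OPTIONAL scopes.
    """

    variables: list[str]
    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def row_set(self) -> set[tuple]:
        return {tuple(row.get(v) for v in self.variables) for row in self.rows}

    def to_csv(self) -> str:
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(self.variables)
        for row in sorted(self.rows, key=lambda r: tuple(str(r.get(v)) for v in self.variables)):
            writer.writerow(["" if row.get(v) is None else row[v] for v in self.variables])
        return buffer.getvalue()

    def to_json(self) -> str:
        doc = {
            "head": {"vars": self.variables},
            "results": {
                "bindings": sorted(
                    (
                        {v: row[v] for v in self.variables if row.get(v) is not None}
                        for row in self.rows
                    ),
                    key=lambda b: tuple(str(b.get(v, "")) for v in self.variables),
                )
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def _scan_algebra(node, denied: set[str]) -> None:
    name = getattr(node, "name", None)
    if name and any(d in name for d in denied):
        raise UnsupportedFeature(f"SPARQL feature not supported: {name}")
    if isinstance(node, dict):
        for value in node.values():
            _scan_algebra(value, denied)
    elif isinstance(node, (list, tuple)):
        for value in node:
            _scan_algebra(value, denied)


def run_select(g: ProvGraphDoc, query: str, bindings: dict | None = None) -> ResultTable:
    """Run a SPARQL 1.1 SELECT (BGP / OPTIONAL / UNION / DISTINCT / FILTER).

    The toolkit's prefixes are always in scope; ``bindings`` pre-binds
    variables by name.
    """
    text = _PREFIX_HEADER + "\n" + query
    try:
        prepared = prepareQuery(text)
    except Exception as exc:
        raise QuerySyntaxError(f"cannot parse SPARQL query: {exc}") from exc
    if prepared.algebra.name != "SelectQuery":
        raise UnsupportedFeature("only SELECT queries are supported")
    _scan_algebra(prepared.algebra, _DENIED_NAMES)
    init = {k: v for k, v in (bindings or {}).items()}
    result = g.graph.query(prepared, initBindings=init)
    variables = [str(v) for v in result.vars]
    rows = []
    seen = set()
    for binding in result:
        bound = binding.asdict()
        row = {var: _plain(bound.get(var)) for var in variables}
        key = tuple(row[v] for v in variables)
        if key not in seen:  # DISTINCT holds even if the query omitted it
            seen.add(key)
            rows.append(row)
    return ResultTable(variables=variables, rows=rows)


def _plain(term):
    if term is None:
        return None
    if isinstance(term, (URIRef, Literal)):
        return str(term)
    return str(term)


# --------------------------------------------------------------------------
# the printed competency queries

def complete_path_experiment(store: ExperimentStore, experiment_id: str) -> ResultTable:
    """The complete experiment path (agents, data, instruments, plans, steps).

    An experiment missing a mandatory component — for example one without
    instruments — yields zero rows rather than an error: the unmatched
    pattern simply eliminates every solution.
    """
    graph = store.merged_graph(experiment_id)
    exp = mint(store.base, "experiment", experiment_id)
    return run_select(graph, LISTING_1, bindings={"experiment": exp})


def complete_path_notebook(store: ExperimentStore, notebook_id: str) -> ResultTable:
    """The complete path of a notebook: steps, runs, run times, variables.

    The first cell has no predecessor, so it contributes no rows — the
    order pattern is not optional in the printed query.
    """
    nb = store.notebook(notebook_id)
    graph = notebook_to_rdf(nb, store.base)
    nbnode = mint(store.base, "notebook", notebook_id)
    return run_select(graph, LISTING_2, bindings={"notebook": nbnode})


# --------------------------------------------------------------------------
# ProvTrack view

#: Containment relations, in tree-assignment priority order.  ``inverse``
#: means the SPARQL pair is (child, parent) rather than (parent, child).
_TREE_RELATIONS: list[tuple[str, URIRef, bool]] = [
    ("prov:wasAttributedTo", PROV.wasAttributedTo, False),
    ("repr:hasDataset", REPR.hasDataset, False),
    ("prov:hadMember", PROV.hadMember, False),
    ("repr:hasPart", REPR.hasPart, False),
    ("repr:hasSetting", REPR.hasSetting, False),
    ("p-plan:isSubPlanOfPlan", PPLAN.isSubPlanOfPlan, True),
    ("p-plan:isStepOfPlan", PPLAN.isStepOfPlan, True),
    ("p-plan:hasInputVar", PPLAN.hasInputVar, False),
    ("p-plan:hasOutputVar", PPLAN.hasOutputVar, False),
    ("p-plan:correspondsToStep", PPLAN.correspondsToStep, True),
    ("repr:reference", REPR.reference, False),
]

#: Cross links shown as extra edges but never as tree parents.
_EDGE_ONLY_RELATIONS: list[tuple[str, URIRef, bool]] = [
    ("p-plan:correspondsToVariable", PPLAN.correspondsToVariable, False),
    ("p-plan:isPrecededBy", PPLAN.isPrecededBy, False),
    ("p-plan:isVariableOfPlan", PPLAN.isVariableOfPlan, True),
    ("p-plan:isInputVarOf", PPLAN.isInputVarOf, True),
    ("p-plan:isOutputVarOf", PPLAN.isOutputVarOf, True),
]

_NODE_TYPE_PRIORITY = [
    (PROV.Agent, "Agent"),
    (PROV.Activity, "Activity"),
    (PPLAN.Step, "Step"),
    (PPLAN.Variable, "Variable"),
    (PPLAN.Plan, "Plan"),
    (REPR.Experiment, "Plan"),
    (REPR.Notebook, "Plan"),
    (PROV.Entity, "Entity"),
]


@dataclass
class ViewNode:
    id: str
    label: str
    node_type: str
    properties: list[tuple[str, str]] = field(default_factory=list)
    children: list[str] = field(default_factory=list)
    parent: str | None = None


@dataclass
class ViewEdge:
    source: str
    target: str
    property: str


@dataclass
class ProvGraphView:
    """Typed node-link tree rooted at an Experiment.

    The view always carries the full tree; expanding and collapsing is a
    client concern ("expand all" is the whole tree, "collapse all" the root
    alone).  Node colours are a client mapping over ``node_type``.
    """

    root: str
    nodes: dict[str, ViewNode]
    edges: list[ViewEdge]

    def to_json(self) -> str:
        doc = {
            "root": self.root,
            "nodes": [
                {
                    "id": n.id,
                    "label": n.label,
                    "type": n.node_type,
                    "parent": n.parent,
                    "properties": [[k, v] for k, v in n.properties],
                    "children": n.children,
                }
                for n in self.nodes.values()
            ],
            "edges": [{"source": e.source, "target": e.target, "property": e.property} for e in self.edges],
        }
        return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def _relation_pairs(graph: ProvGraphDoc, predicate: URIRef, inverse: bool) -> list[tuple[str, str]]:
    # one small SELECT per relation family: the query-splitting strategy
    table = run_select(graph, f"SELECT ?s ?o WHERE {{ ?s <{predicate}> ?o . FILTER(isIRI(?o)) }}")
    pairs = [(row["s"], row["o"]) for row in table.rows]
    if inverse:
        pairs = [(o, s) for s, o in pairs]
    return sorted(pairs)


def _term_name(term: URIRef) -> str:
    text = str(term)
    for prefix, ns in PREFIXES.items():
        if text.startswith(str(ns)):
            return f"{prefix}:{text[len(str(ns)):]}"
    return text


def build_view_from_graph(graph: ProvGraphDoc, root: URIRef) -> ProvGraphView:
    """Assemble the typed node-link tree from per-family split queries."""
    tree_pairs = {name: _relation_pairs(graph, pred, inv) for name, pred, inv in _TREE_RELATIONS}
    edge_pairs = {name: _relation_pairs(graph, pred, inv) for name, pred, inv in _EDGE_ONLY_RELATIONS}

    nodes: dict[str, ViewNode] = {}
    edges: list[ViewEdge] = []

    def make_node(iri: str) -> ViewNode:
        subject = URIRef(iri)
        types = set(graph.objects(subject, RDF.type))
        node_type = next((label for cls, label in _NODE_TYPE_PRIORITY if cls in types), "Entity")
        names = [str(o) for o in graph.objects(subject, REPR.name)]
        properties = sorted(
            (_term_name(p), str(o))
            for p, o in ((p, o) for _, p, o in graph.graph.triples((subject, None, None)))
            if isinstance(o, Literal)
        )
        return ViewNode(id=iri, label=min(names) if names else iri_leaf(subject), node_type=node_type, properties=properties)

    root_id = str(root)
    nodes[root_id] = make_node(root_id)
    frontier = [root_id]
    while frontier:
        current = frontier.pop(0)
        for name, _, _ in _TREE_RELATIONS:
            for parent, child in tree_pairs[name]:
                if parent != current:
                    continue
                edges.append(ViewEdge(parent, child, name))
                if child not in nodes:
                    node = make_node(child)
                    node.parent = parent
                    nodes[child] = node
                    nodes[parent].children.append(child)
                    frontier.append(child)
    for name, _, _ in _EDGE_ONLY_RELATIONS:
        for parent, child in edge_pairs[name]:
            edges.append(ViewEdge(parent, child, name))
    return ProvGraphView(root=root_id, nodes=nodes, edges=edges)


def build_provtrack_view(store: ExperimentStore, experiment_id: str) -> ProvGraphView:
    graph = store.merged_graph(experiment_id)
    return build_view_from_graph(graph, mint(store.base, "experiment", experiment_id))


def path_to_root(view: ProvGraphView, node_id: str) -> list[str]:
    """Node ids from a node up to the Experiment root (inclusive)."""
    if node_id not in view.nodes:
        raise UnknownNode(f"no node {node_id!r} in view")
    path = [node_id]
    while view.nodes[path[-1]].parent is not None:
        path.append(view.nodes[path[-1]].parent)
    return path


def search_view(view: ProvGraphView, term: str, scope: str = "nodes") -> list:
    """Case-insensitive substring search over node labels or edge names.

    An empty term matches everything in scope; results keep document
    (insertion) order.
    """
    needle = term.lower()
    if scope == "nodes":
        return [n.id for n in view.nodes.values() if needle in n.label.lower()]
    if scope == "edges":
        return [e for e in view.edges if needle in e.property.lower()]
    raise ValueError(f"unknown search scope {scope!r}")
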