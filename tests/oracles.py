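"""Independent oracles used by the test suite.

These deliberately re-derive expected values by a different route than the
implementation: brute-force LCS by memoized recursion, competency-query
answers by nested-loop joins over the in-memory records, triple counts by
enumerating the mapping table, and graph traversal directly over rdflib
triples.  None of them calls the code path it checks.
"""

from __future__ import annotations

from functools import lru_cache

from rdflib import URIRef
from rdflib.namespace import RDF

from provlink.experiment import ExperimentRecord, ExperimentStore
from provlink.notebook import Notebook, format_timestamp
from provlink.rdf import mint
from provlink.vocab import PPLAN


# --------------------------------------------------------------------------
# LCS by memoized recursion (diff oracle)

def lcs_length(a: tuple, b: tuple) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def minimal_edit_cost(left: str, right: str) -> int:
    """Fewest deleted + inserted lines turning left into right."""
    a = tuple(left.split("\n")) if left else ()
    b = tuple(right.split("\n")) if right else ()
    common = lcs_length(a, b)
    return (len(a) - common) + (len(b) - common)


# --------------------------------------------------------------------------
# notebook mapping enumeration (triple-count oracle)

def expected_notebook_triples(nb: Notebook) -> int:
    """Count the triples the notebook mapping must emit, rule by rule."""
    count = 2  # notebook type triples
    if nb.environment is not None:
        attrs = 5 + len(nb.environment.packages)
        count += 4 * attrs  # hasSetting + type + name + value per attribute
    code = nb.code_cells()
    count += 3 * len(code)  # step: type + isStepOfPlan + name
    count += max(len(code) - 1, 0)  # isPrecededBy chain
    count += 2 * 6 * len(code)  # two variables x (type, link, inverse, planlink, value, name)
    records = sum(len(c.executions) for c in code)
    count += 6 * records  # type, correspondsToStep, started, ended, executionTime, snapshot
    count += 3 * sum(1 for c in nb.cells if c.cell_type != "code")  # hasPart + type + payload
    return count


def expected_experiment_triples(e: ExperimentRecord) -> dict[str, int]:
    """Predicate-level counts implied by the experiment mapping."""
    n_images = sum(len(d.images) for d in e.datasets)
    n_parts = sum(len(i.parts) for i in e.instruments)
    n_part_settings = sum(len(p.settings) for i in e.instruments for p in i.parts)
    n_vars = sum(len(s.inputs) + len(s.outputs) for s in e.steps)
    return {
        "wasAttributedTo": len(e.agents),
        "hasRole": len(e.agents),
        "hasDataset": len(e.datasets),
        "hadMember": n_images,
        "hasPart": len(e.instruments) + n_parts + len(e.materials),
        "hasSetting": n_part_settings + len(e.settings),
        "correspondsToVariable": sum(len(i.linked_images) for i in e.instruments),
        "isSubPlanOfPlan": len(e.subplans),
        "isStepOfPlan": len(e.steps),
        "isPrecededBy": sum(1 for s in e.steps if s.predecessor is not None),
        "isVariableOfPlan": n_vars,
        "hasInputVar": sum(len(s.inputs) for s in e.steps),
        "hasOutputVar": sum(len(s.outputs) for s in e.steps),
        "isAvailableAt": sum(
            1 for s in e.steps for v in s.inputs + s.outputs if v.availability_url
        ),
        "reference": sum(1 for s in e.steps for v in s.inputs + s.outputs if v.reference),
        "generatedAtTime": 1,
    }


# --------------------------------------------------------------------------
# competency-query oracles (nested-loop joins over in-memory records)

_VARIABLE_TYPE = str(PPLAN.Variable)


def oracle_listing2_rows(nb: Notebook, base: str) -> set[tuple]:
    """Rows of the notebook complete-path query, by direct enumeration.

    Join order mirrors the printed pattern: steps of the notebook, their
    executions with run times, one input and one output variable each, and
    the mandatory predecessor — which excludes the first code cell.
    """
    rows = set()
    nbnode = str(mint(base, "notebook", nb.stable_id))
    code = nb.code_cells()
    for i, cell in enumerate(code):
        if i == 0:
            continue  # no isPrecededBy binding
        step = str(mint(base, "cell", cell.stable_id))
        previous = str(mint(base, "cell", code[i - 1].stable_id))
        invar = str(mint(base, "variable", cell.stable_id, "in"))
        outvar = str(mint(base, "variable", cell.stable_id, "out"))
        for record in cell.executions:
            execution = str(
                mint(
                    base,
                    "execution",
                    cell.stable_id,
                    f"{format_timestamp(record.start_time)}-{record.sequence_index}",
                )
            )
            rows.add(
                (step, nbnode, execution, str(record.elapsed_ms), invar, outvar, previous)
            )
    return rows


LISTING_2_VARS = ["step", "notebook", "execution", "executionTime", "inputVar", "outputVar", "previousStep"]

LISTING_1_VARS = [
    "experiment", "agent", "dataset", "generatedAtTime", "role", "image",
    "instrument", "instrument_part", "setting", "plan", "variable", "step",
    "previousStep", "Input", "InputType", "InputName", "Output", "OutputType",
    "OutputName", "outputUrl", "OutputReference", "OutputReferenceValue",
]


def oracle_listing1_rows(store: ExperimentStore, experiment_id: str) -> set[tuple]:
    """Rows of the experiment complete-path query, by nested-loop join.

    Enumerates agents x (dataset, image) x (instrument, part, setting)
    joined on the image, x (plan, variable) over sub-plans and attached
    notebooks, x experiment-level steps, with the input/output UNION and
    its OPTIONAL blocks.
    """
    base = store.base
    e = store.experiments[experiment_id]
    exp = str(mint(base, "experiment", experiment_id))
    generated = e.generated_at.isoformat()  # XSD-normalized dateTime lexical

    # (plan, variable) pairs: sub-plan step variables and notebook variables
    plan_vars: list[tuple[str, str]] = []
    for plan in e.subplans:
        pnode = str(mint(base, "plan", plan.id))
        for step in e.steps:
            if step.plan_id == plan.id:
                for v in step.inputs + step.outputs:
                    plan_vars.append((pnode, str(mint(base, "variable", v.id))))
    for notebook_id in store.links.get(experiment_id, []):
        nb = store.notebook(notebook_id)
        nbnode = str(mint(base, "notebook", nb.stable_id))
        for cell in nb.code_cells():
            for direction in ("in", "out"):
                plan_vars.append((nbnode, str(mint(base, "variable", cell.stable_id, direction))))

    instrument_rows = []  # (instrument, part, setting) joined on image id
    for inst in e.instruments:
        inode = str(mint(base, "instrument", inst.id))
        for image_id in inst.linked_images:
            for part in inst.parts:
                pnode = str(mint(base, "part", part.id))
                for setting in part.settings:
                    snode = str(mint(base, "setting", part.id, setting.key))
                    instrument_rows.append((image_id, inode, pnode, snode))

    def union_branches(step):
        step_node = str(mint(base, "step", step.id))
        previous = str(mint(base, "step", step.predecessor)) if step.predecessor else None
        for v in step.inputs:
            yield step_node, previous, {
                "Input": str(mint(base, "variable", v.id)),
                "InputType": _VARIABLE_TYPE,
                "InputName": v.name,
            }
        for v in step.outputs:
            ref = str(mint(base, "reference", v.id)) if v.reference else None
            yield step_node, previous, {
                "Output": str(mint(base, "variable", v.id)),
                "OutputType": _VARIABLE_TYPE,
                "OutputName": v.name,
                "outputUrl": v.availability_url,
                "OutputReference": ref,
                "OutputReferenceValue": v.reference if ref else None,
            }

    rows = set()
    for agent in e.agents:
        anode = str(mint(base, "agent", agent.id))
        for ds in e.datasets:
            dnode = str(mint(base, "dataset", ds.id))
            for image in ds.images:
                inode_img = str(mint(base, "image", image.id))
                for image_id, inst, part, setting in instrument_rows:
                    if image_id != image.id:
                        continue
                    for plan, variable in plan_vars:
                        for step in e.steps:
                            if step.plan_id != experiment_id:
                                continue
                            for step_node, previous, branch in union_branches(step):
                                binding = {
                                    "experiment": exp,
                                    "agent": anode,
                                    "dataset": dnode,
                                    "generatedAtTime": generated,
                                    "role": agent.role,
                                    "image": inode_img,
                                    "instrument": inst,
                                    "instrument_part": part,
                                    "setting": setting,
                                    "plan": plan,
                                    "variable": variable,
                                    "step": step_node,
                                    "previousStep": previous,
                                }
                                binding.update(branch)
                                rows.add(tuple(binding.get(v) for v in LISTING_1_VARS))
    return rows


# --------------------------------------------------------------------------
# monolithic graph traversal (ProvTrack equivalence oracle)

_OBJECT_PROPERTIES_FORWARD = {
    "wasAttributedTo", "hasDataset", "hadMember", "hasPart", "hasSetting",
    "hasInputVar", "hasOutputVar", "reference", "correspondsToVariable", "isPrecededBy",
}
_OBJECT_PROPERTIES_INVERSE = {
    "isSubPlanOfPlan", "isStepOfPlan", "correspondsToStep", "isVariableOfPlan",
    "isInputVarOf", "isOutputVarOf",
}


def reachable_individuals(graph, root: URIRef) -> set[str]:
    """All IRIs reachable from the root by one monolithic traversal."""
    forward: dict[URIRef, set[URIRef]] = {}
    for s, p, o in graph.graph:
        if p == RDF.type or not isinstance(o, URIRef):
            continue
        name = str(p).rsplit("#", 1)[-1]
        if name in _OBJECT_PROPERTIES_FORWARD:
            forward.setdefault(s, set()).add(o)
        if name in _OBJECT_PROPERTIES_INVERSE:
            forward.setdefault(o, set()).add(s)
    seen = {root}
    stack = [root]
    while stack:
        for nxt in forward.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return {str(n) for n in seen}
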