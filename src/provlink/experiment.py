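"""Experiment metadata: the eight-component model, versions, RDF export.

An experiment description links everything that happened on the way to a
result: the people involved (agents with roles), the data produced
(datasets of images), the instruments with their parts and settings, the
materials (chemicals, plasmids, proteins...), the plans followed (standard
operating procedures, computational notebooks), the concrete steps with
their input and output variables, and experiment-level settings.  An
experiment is itself a plan — it exports as a node typed both
``repr:Experiment`` and ``p-plan:Plan`` — and a computational notebook
attaches to it as a sub-plan, which is how non-computational lab work and
notebook executions end up in one queryable graph.

Every mutation of a record stored in an :class:`ExperimentStore`
auto-saves a full snapshot as a new :class:`VersionedDescription`, so the
version history can be listed and any two versions compared field by field.
The store persists as a single JSON document: portable and diffable.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .errors import (
    CycleDetected,
    NotAProvlinkGraph,
    UnknownExperiment,
    UnknownNotebook,
    UnknownReference,
    UnknownVersion,
)
from .notebook import Notebook, ensure_stable_ids, format_timestamp, parse_timestamp, read_notebook, to_utc_ms, write_notebook
from .rdf import DEFAULT_BASE, ProvGraphDoc, mint, notebook_to_rdf
from .vocab import PPLAN, PROV, REPR


# --------------------------------------------------------------------------
# record types

@dataclass
class AgentRef:
    id: str
    name: str
    role: str


@dataclass
class ImageRef:
    id: str
    name: str


@dataclass
class DatasetRef:
    id: str
    name: str
    images: list[ImageRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [img.id for img in self.images]
        if len(ids) != len(set(ids)):
            raise UnknownReference(f"duplicate image ids in dataset {self.id}")


@dataclass
class SettingEntry:
    """One key-value(-unit) instrument or experiment setting."""

    key: str
    value: str | int | float
    unit: str | None = None

    def __post_init__(self) -> None:
        if not self.key:
            raise UnknownReference("setting key must be non-empty")

    @property
    def display_value(self) -> str:
        return f"{self.value} {self.unit}" if self.unit else str(self.value)


@dataclass
class InstrumentPart:
    id: str
    name: str
    settings: list[SettingEntry] = field(default_factory=list)


@dataclass
class InstrumentRecord:
    id: str
    name: str
    parts: list[InstrumentPart] = field(default_factory=list)
    linked_images: list[str] = field(default_factory=list)  # image ids


@dataclass
class MaterialRecord:
    id: str
    kind: str  # chemical, plasmid, protein, ...
    name: str
    attributes: dict = field(default_factory=dict)


@dataclass
class PlanRecord:
    id: str
    kind: str  # sop | notebook | other
    name: str
    body: str = ""


@dataclass
class VariableRecord:
    id: str
    name: str | None = None
    var_type: str = "Variable"
    availability_url: str | None = None
    reference: str | None = None


@dataclass
class StepRecord:
    id: str
    plan_id: str
    name: str
    predecessor: str | None = None
    inputs: list[VariableRecord] = field(default_factory=list)
    outputs: list[VariableRecord] = field(default_factory=list)


@dataclass
class ExperimentRecord:
    id: str
    title: str
    generated_at: datetime
    agents: list[AgentRef] = field(default_factory=list)
    datasets: list[DatasetRef] = field(default_factory=list)
    instruments: list[InstrumentRecord] = field(default_factory=list)
    materials: list[MaterialRecord] = field(default_factory=list)
    subplans: list[PlanRecord] = field(default_factory=list)
    steps: list[StepRecord] = field(default_factory=list)
    settings: list[SettingEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.generated_at = to_utc_ms(self.generated_at)

    def plan_ids(self) -> set[str]:
        return {self.id} | {p.id for p in self.subplans}

    def image_ids(self) -> set[str]:
        return {img.id for ds in self.datasets for img in ds.images}

    def step_by_id(self, step_id: str) -> StepRecord:
        for s in self.steps:
            if s.id == step_id:
                return s
        raise UnknownReference(f"no step {step_id!r}")


@dataclass
class VersionedDescription:
    entity_id: str
    version: int
    saved_at: datetime
    author: str | None
    content: dict


# --------------------------------------------------------------------------
# the store

class ExperimentStore:
    """Experiments, their version histories, and linked notebooks.

    ``clock`` is any callable returning a timezone-aware datetime; version
    save times are forced strictly increasing even if the clock stalls.
    """

    def __init__(self, base: str = DEFAULT_BASE, clock=None):
        self.base = base
        self.experiments: dict[str, ExperimentRecord] = {}
        self.notebooks: dict[str, str] = {}  # notebook stable_id -> document text
        self.links: dict[str, list[str]] = {}  # experiment id -> notebook ids
        self.versions: dict[str, list[VersionedDescription]] = {}
        self._clock = clock or (lambda: datetime.now(timezone.utc))
        self._last_saved: datetime | None = None

    # -- versioning ---------------------------------------------------------

    def _snapshot(self, record: ExperimentRecord, author: str | None) -> None:
        saved_at = to_utc_ms(self._clock())
        if self._last_saved is not None and saved_at <= self._last_saved:
            saved_at = self._last_saved + timedelta(milliseconds=1)
        self._last_saved = saved_at
        history = self.versions.setdefault(record.id, [])
        history.append(
            VersionedDescription(
                entity_id=record.id,
                version=len(history) + 1,
                saved_at=saved_at,
                author=author,
                content=record_to_json(record),
            )
        )

    def version_history(self, entity_id: str) -> list[VersionedDescription]:
        if entity_id not in self.versions:
            raise UnknownReference(f"no versions for {entity_id!r}")
        return list(self.versions[entity_id])

    def compare_versions(self, entity_id: str, v_left: int, v_right: int) -> list[dict]:
        """Field-level changes between two versions of an entity.

        Each change is ``{"path", "kind" (added|removed|changed), "old",
        "new"}``; paths use dotted/indexed notation like ``datasets[0].name``.
        """
        history = self.version_history(entity_id)
        by_version = {v.version: v for v in history}
        for v in (v_left, v_right):
            if v not in by_version:
                raise UnknownVersion(f"{entity_id!r} has no version {v}")
        return _dict_diff(by_version[v_left].content, by_version[v_right].content)

    # -- experiment mutations -----------------------------------------------

    def _get(self, experiment_id: str) -> ExperimentRecord:
        if experiment_id not in self.experiments:
            raise UnknownExperiment(f"no experiment {experiment_id!r}")
        return self.experiments[experiment_id]

    def create_experiment(
        self,
        experiment_id: str,
        title: str,
        generated_at: datetime,
        agents: list[AgentRef] | None = None,
        author: str | None = None,
    ) -> ExperimentRecord:
        if experiment_id in self.experiments:
            raise UnknownReference(f"experiment {experiment_id!r} already exists")
        record = ExperimentRecord(id=experiment_id, title=title, generated_at=generated_at, agents=list(agents or []))
        self.experiments[experiment_id] = record
        self._snapshot(record, author)
        return record

    def _mutate(self, experiment_id: str, author: str | None, apply) -> ExperimentRecord:
        record = self._get(experiment_id)
        apply(record)
        self._snapshot(record, author)
        return record

    def set_title(self, experiment_id: str, title: str, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: setattr(r, "title", title))

    def add_agent(self, experiment_id: str, agent: AgentRef, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: r.agents.append(agent))

    def add_dataset(self, experiment_id: str, dataset: DatasetRef, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: r.datasets.append(dataset))

    def add_instrument(self, experiment_id: str, instrument: InstrumentRecord, author: str | None = None) -> ExperimentRecord:
        record = self._get(experiment_id)
        unknown = set(instrument.linked_images) - record.image_ids()
        if unknown:
            raise UnknownReference(f"instrument links unknown images: {sorted(unknown)}")
        return self._mutate(experiment_id, author, lambda r: r.instruments.append(instrument))

    def add_material(self, experiment_id: str, material: MaterialRecord, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: r.materials.append(material))

    def add_subplan(self, experiment_id: str, plan: PlanRecord, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: r.subplans.append(plan))

    def add_setting(self, experiment_id: str, setting: SettingEntry, author: str | None = None) -> ExperimentRecord:
        return self._mutate(experiment_id, author, lambda r: r.settings.append(setting))

    def add_step(self, experiment_id: str, step: StepRecord, author: str | None = None) -> ExperimentRecord:
        record = self._get(experiment_id)
        if step.plan_id not in record.plan_ids():
            raise UnknownReference(f"step plan {step.plan_id!r} is not this experiment or a subplan")
        if step.predecessor is not None:
            pred = record.step_by_id(step.predecessor)
            if pred.plan_id != step.plan_id:
                raise UnknownReference("step predecessor must belong to the same plan")
        _check_acyclic(record.steps + [step])
        return self._mutate(experiment_id, author, lambda r: r.steps.append(step))

    def set_predecessor(self, experiment_id: str, step_id: str, predecessor: str | None, author: str | None = None) -> ExperimentRecord:
        record = self._get(experiment_id)
        step = record.step_by_id(step_id)
        if predecessor is not None:
            pred = record.step_by_id(predecessor)
            if pred.plan_id != step.plan_id:
                raise UnknownReference("step predecessor must belong to the same plan")
        trial = copy.deepcopy(record.steps)
        next(s for s in trial if s.id == step_id).predecessor = predecessor
        _check_acyclic(trial)
        return self._mutate(experiment_id, author, lambda r: setattr(r.step_by_id(step_id), "predecessor", predecessor))

    # -- notebooks -----------------------------------------------------------

    def link_notebook(self, experiment_id: str, nb: Notebook | str, author: str | None = None) -> str:
        """Store a notebook document and link it to an experiment as a sub-plan."""
        record = self._get(experiment_id)
        notebook = read_notebook(nb) if isinstance(nb, str) else nb
        ensure_stable_ids(notebook)
        self.notebooks[notebook.stable_id] = write_notebook(notebook)
        self.links.setdefault(record.id, [])
        if notebook.stable_id not in self.links[record.id]:
            self.links[record.id].append(notebook.stable_id)
        self._snapshot(record, author)
        return notebook.stable_id

    def notebook(self, notebook_id: str) -> Notebook:
        if notebook_id not in self.notebooks:
            raise UnknownNotebook(f"no notebook {notebook_id!r}")
        return read_notebook(self.notebooks[notebook_id])

    def experiment_of_notebook(self, notebook_id: str) -> str:
        for experiment_id, notebook_ids in self.links.items():
            if notebook_id in notebook_ids:
                return experiment_id
        raise UnknownNotebook(f"notebook {notebook_id!r} is not linked to any experiment")

    # -- graphs --------------------------------------------------------------

    def merged_graph(self, experiment_id: str) -> ProvGraphDoc:
        """The experiment graph with every linked notebook attached."""
        record = self._get(experiment_id)
        graph = experiment_to_rdf(record, self.base)
        for notebook_id in self.links.get(experiment_id, []):
            nb_graph = notebook_to_rdf(self.notebook(notebook_id), self.base)
            graph = attach_notebook_provenance(record, nb_graph, self.base, merged=graph)
        return graph

    # -- persistence ---------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema": 1,
            "base": self.base,
            "experiments": {k: record_to_json(v) for k, v in sorted(self.experiments.items())},
            "notebooks": dict(sorted(self.notebooks.items())),
            "links": {k: list(v) for k, v in sorted(self.links.items())},
            "versions": {
                k: [
                    {
                        "entity_id": v.entity_id,
                        "version": v.version,
                        "saved_at": format_timestamp(v.saved_at),
                        "author": v.author,
                        "content": v.content,
                    }
                    for v in vs
                ]
                for k, vs in sorted(self.versions.items())
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n"

    @classmethod
    def from_json(cls, text: str, clock=None) -> "ExperimentStore":
        doc = json.loads(text)
        store = cls(base=doc.get("base", DEFAULT_BASE), clock=clock)
        store.experiments = {k: record_from_json(v) for k, v in doc.get("experiments", {}).items()}
        store.notebooks = dict(doc.get("notebooks", {}))
        store.links = {k: list(v) for k, v in doc.get("links", {}).items()}
        store.versions = {
            k: [
                VersionedDescription(
                    entity_id=v["entity_id"],
                    version=v["version"],
                    saved_at=parse_timestamp(v["saved_at"]),
                    author=v.get("author"),
                    content=v["content"],
                )
                for v in vs
            ]
            for k, vs in doc.get("versions", {}).items()
        }
        saved = [v.saved_at for vs in store.versions.values() for v in vs]
        store._last_saved = max(saved) if saved else None
        return store


def _check_acyclic(steps: list[StepRecord]) -> None:
    pred = {s.id: s.predecessor for s in steps}
    for start in pred:
        seen = {start}
        current = pred.get(start)
        while current is not None:
            if current in seen:
                raise CycleDetected(f"step predecessor cycle through {current!r}")
            seen.add(current)
            current = pred.get(current)


# --------------------------------------------------------------------------
# JSON (de)serialization of records

def record_to_json(record: ExperimentRecord) -> dict:
    obj = dataclasses.asdict(record)
    obj["generated_at"] = format_timestamp(record.generated_at)
    return obj


def record_from_json(obj: dict) -> ExperimentRecord:
    return ExperimentRecord(
        id=obj["id"],
        title=obj["title"],
        generated_at=parse_timestamp(obj["generated_at"]),
        agents=[AgentRef(**a) for a in obj.get("agents", [])],
        datasets=[
            DatasetRef(id=d["id"], name=d["name"], images=[ImageRef(**i) for i in d.get("images", [])])
            for d in obj.get("datasets", [])
        ],
        instruments=[
            InstrumentRecord(
                id=i["id"],
                name=i["name"],
                parts=[
                    InstrumentPart(id=p["id"], name=p["name"], settings=[SettingEntry(**s) for s in p.get("settings", [])])
                    for p in i.get("parts", [])
                ],
                linked_images=list(i.get("linked_images", [])),
            )
            for i in obj.get("instruments", [])
        ],
        materials=[MaterialRecord(**m) for m in obj.get("materials", [])],
        subplans=[PlanRecord(**p) for p in obj.get("subplans", [])],
        steps=[
            StepRecord(
                id=s["id"],
                plan_id=s["plan_id"],
                name=s["name"],
                predecessor=s.get("predecessor"),
                inputs=[VariableRecord(**v) for v in s.get("inputs", [])],
                outputs=[VariableRecord(**v) for v in s.get("outputs", [])],
            )
            for s in obj.get("steps", [])
        ],
        settings=[SettingEntry(**s) for s in obj.get("settings", [])],
    )


def _dict_diff(left, right, path: str = "") -> list[dict]:
    changes: list[dict] = []
    if isinstance(left, dict) and isinstance(right, dict):
        for key in sorted(set(left) | set(right)):
            sub = f"{path}.{key}" if path else key
            if key not in left:
                changes.append({"path": sub, "kind": "added", "old": None, "new": right[key]})
            elif key not in right:
                changes.append({"path": sub, "kind": "removed", "old": left[key], "new": None})
            else:
                changes.extend(_dict_diff(left[key], right[key], sub))
    elif isinstance(left, list) and isinstance(right, list):
        for i in range(max(len(left), len(right))):
            sub = f"{path}[{i}]"
            if i >= len(left):
                changes.append({"path": sub, "kind": "added", "old": None, "new": right[i]})
            elif i >= len(right):
                changes.append({"path": sub, "kind": "removed", "old": left[i], "new": None})
            else:
                changes.extend(_dict_diff(left[i], right[i], sub))
    elif left != right:
        changes.append({"path": path, "kind": "changed", "old": left, "new": right})
    return changes


# --------------------------------------------------------------------------
# RDF export

def experiment_to_rdf(e: ExperimentRecord, base: str = DEFAULT_BASE) -> ProvGraphDoc:
    """Materialize an experiment description in the closed vocabulary.

    A minimal experiment (no components, empty title) exports exactly its
    two type triples and ``prov:generatedAtTime``.
    """
    g = ProvGraphDoc()
    exp = mint(base, "experiment", e.id)
    g.add(exp, RDF.type, REPR.Experiment)
    g.add(exp, RDF.type, PPLAN.Plan)
    g.add(exp, PROV.generatedAtTime, Literal(format_timestamp(e.generated_at), datatype=XSD.dateTime))
    if e.title:
        g.add(exp, REPR.name, Literal(e.title))

    for agent in e.agents:
        anode = mint(base, "agent", agent.id)
        g.add(exp, PROV.wasAttributedTo, anode)
        g.add(anode, RDF.type, PROV.Agent)
        g.add(anode, REPR.name, Literal(agent.name))
        g.add(anode, REPR.hasRole, Literal(agent.role))

    image_nodes: dict[str, URIRef] = {}
    for ds in e.datasets:
        dnode = mint(base, "dataset", ds.id)
        g.add(exp, REPR.hasDataset, dnode)
        g.add(dnode, RDF.type, PROV.Entity)
        g.add(dnode, REPR.name, Literal(ds.name))
        for image in ds.images:
            inode = mint(base, "image", image.id)
            image_nodes[image.id] = inode
            g.add(dnode, PROV.hadMember, inode)
            g.add(inode, RDF.type, PROV.Entity)
            g.add(inode, REPR.name, Literal(image.name))

    for instrument in e.instruments:
        inode = mint(base, "instrument", instrument.id)
        g.add(exp, REPR.hasPart, inode)
        g.add(inode, RDF.type, PROV.Entity)
        g.add(inode, REPR.name, Literal(instrument.name))
        for image_id in instrument.linked_images:
            if image_id not in image_nodes:
                raise UnknownReference(f"instrument {instrument.id} links unknown image {image_id!r}")
            g.add(inode, PPLAN.correspondsToVariable, image_nodes[image_id])
        for part in instrument.parts:
            pnode = mint(base, "part", part.id)
            g.add(inode, REPR.hasPart, pnode)
            g.add(pnode, RDF.type, PROV.Entity)
            g.add(pnode, REPR.name, Literal(part.name))
            _add_settings(g, base, pnode, part.id, part.settings)

    _add_settings(g, base, exp, e.id, e.settings)

    for material in e.materials:
        mnode = mint(base, "material", material.id)
        g.add(exp, REPR.hasPart, mnode)
        g.add(mnode, RDF.type, PROV.Entity)
        g.add(mnode, REPR.name, Literal(material.name))
        payload = {"kind": material.kind, "attributes": material.attributes}
        g.add(mnode, RDF.value, Literal(json.dumps(payload, sort_keys=True)))

    plan_nodes: dict[str, URIRef] = {e.id: exp}
    for plan in e.subplans:
        pnode = mint(base, "plan", plan.id)
        plan_nodes[plan.id] = pnode
        g.add(pnode, RDF.type, PPLAN.Plan)
        g.add(pnode, PPLAN.isSubPlanOfPlan, exp)
        g.add(pnode, REPR.name, Literal(plan.name))
        if plan.body:
            g.add(pnode, RDF.value, Literal(plan.body))

    step_nodes: dict[str, URIRef] = {}
    for step in e.steps:
        snode = mint(base, "step", step.id)
        step_nodes[step.id] = snode
        g.add(snode, RDF.type, PPLAN.Step)
        g.add(snode, PPLAN.isStepOfPlan, plan_nodes[step.plan_id])
        g.add(snode, REPR.name, Literal(step.name))
    for step in e.steps:
        if step.predecessor is not None:
            g.add(step_nodes[step.id], PPLAN.isPrecededBy, step_nodes[step.predecessor])
        for variable, direction in [(v, "in") for v in step.inputs] + [(v, "out") for v in step.outputs]:
            vnode = mint(base, "variable", variable.id)
            g.add(vnode, RDF.type, PPLAN.Variable)
            g.add(vnode, PPLAN.isVariableOfPlan, plan_nodes[step.plan_id])
            if direction == "in":
                g.add(step_nodes[step.id], PPLAN.hasInputVar, vnode)
                g.add(vnode, PPLAN.isInputVarOf, step_nodes[step.id])
            else:
                g.add(step_nodes[step.id], PPLAN.hasOutputVar, vnode)
                g.add(vnode, PPLAN.isOutputVarOf, step_nodes[step.id])
            if variable.name:
                g.add(vnode, REPR.name, Literal(variable.name))
            if variable.availability_url:
                g.add(vnode, REPR.isAvailableAt, Literal(variable.availability_url))
            if variable.reference:
                rnode = mint(base, "reference", variable.id)
                g.add(vnode, REPR.reference, rnode)
                g.add(rnode, RDF.type, PROV.Entity)
                g.add(rnode, RDF.value, Literal(variable.reference))
    return g


def _add_settings(g: ProvGraphDoc, base: str, owner: URIRef, owner_id: str, settings: list[SettingEntry]) -> None:
    for setting in settings:
        snode = mint(base, "setting", owner_id, setting.key)
        g.add(owner, REPR.hasSetting, snode)
        g.add(snode, RDF.type, PROV.Entity)
        g.add(snode, REPR.name, Literal(setting.key))
        g.add(snode, RDF.value, Literal(setting.display_value))


def attach_notebook_provenance(
    e: ExperimentRecord,
    nb_graph: ProvGraphDoc,
    base: str = DEFAULT_BASE,
    merged: ProvGraphDoc | None = None,
) -> ProvGraphDoc:
    """Link a notebook's provenance graph to an experiment.

    The merged graph is the union of the experiment's export and the
    notebook graph plus one linking triple, notebook
    ``p-plan:isSubPlanOfPlan`` experiment.  Idempotent under set semantics.
    """
    nbnodes = set(nb_graph.subjects(RDF.type, REPR.Notebook))
    if len(nbnodes) != 1:
        raise NotAProvlinkGraph(f"expected exactly one repr:Notebook node, found {len(nbnodes)}")
    result = (merged if merged is not None else experiment_to_rdf(e, base)).union(nb_graph)
    result.add(next(iter(nbnodes)), PPLAN.isSubPlanOfPlan, mint(base, "experiment", e.id))
    return result
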