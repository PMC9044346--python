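"""Experiment records, auto-versioning, and RDF export."""

from datetime import datetime, timezone

import pytest
from rdflib.namespace import RDF

from provlink import (
    AgentRef,
    DatasetRef,
    ExperimentStore,
    FixtureSpec,
    ImageRef,
    InstrumentPart,
    InstrumentRecord,
    SettingEntry,
    StepRecord,
    attach_notebook_provenance,
    experiment_to_rdf,
    generate_notebook,
    notebook_to_rdf,
    serialize_turtle,
)
from provlink.errors import CycleDetected, NotAProvlinkGraph, UnknownReference, UnknownVersion
from provlink.fixtures import generate_store
from provlink.rdf import ProvGraphDoc
from provlink.vocab import PPLAN, PROV, REPR

from oracles import expected_experiment_triples

T0 = datetime(2019, 4, 21, tzinfo=timezone.utc)


def fresh_store():
    tick = iter(range(1, 10_000))
    return ExperimentStore(clock=lambda: datetime(2020, 1, 1, 0, 0, next(tick), tzinfo=timezone.utc))


@pytest.fixture
def screen_store():
    """The condensation-screen fixture: 1 agent, 1 dataset of 2 images,
    1 instrument with 1 part carrying 2 settings."""
    store = fresh_store()
    store.create_experiment(
        "screen-1",
        "Focused mitotic chromosome condensation screen using HeLa cells",
        T0,
        agents=[AgentRef("a1", "J. Doe", "screening scientist")],
    )
    store.add_dataset("screen-1", DatasetRef("ds1", "plate 1", images=[ImageRef("i1", "well A1"), ImageRef("i2", "well A2")]))
    store.add_instrument(
        "screen-1",
        InstrumentRecord(
            "inst1",
            "spinning disk confocal",
            parts=[InstrumentPart("p1", "camera", settings=[
                SettingEntry("exposure time", 50, "ms"),
                SettingEntry("binning", 2),
            ])],
            linked_images=["i1", "i2"],
        ),
    )
    return store


class TestCreateAndExport:
    def test_minimal_experiment_exports_types_and_timestamp_only(self):
        store = fresh_store()
        record = store.create_experiment("e1", "", T0)
        g = experiment_to_rdf(record)
        assert len(g) == 3
        predicates = {p for _, p, _ in g.triples()}
        assert predicates == {RDF.type, PROV.generatedAtTime}

    def test_screen_fixture_export_matches_mapping_enumeration(self, screen_store):
        record = screen_store.experiments["screen-1"]
        g = experiment_to_rdf(record)
        by_name = {}
        for _, p, _ in g.triples():
            by_name[str(p).rsplit("#", 1)[-1]] = by_name.get(str(p).rsplit("#", 1)[-1], 0) + 1
        expected = expected_experiment_triples(record)
        assert by_name.get("hasDataset", 0) == expected["hasDataset"] == 1
        assert by_name.get("hadMember", 0) == expected["hadMember"] == 2
        assert by_name.get("hasPart", 0) == expected["hasPart"] == 2  # instrument + its part
        assert by_name.get("hasSetting", 0) == expected["hasSetting"] == 2
        assert by_name.get("correspondsToVariable", 0) == expected["correspondsToVariable"] == 2
        for name, count in expected.items():
            assert by_name.get(name, 0) == count, name

    @pytest.mark.parametrize("profile", ["minimal", "cpcf", "palm_dstorm", "screen"])
    def test_generated_profiles_match_enumeration(self, profile):
        store, experiment_id = generate_store(FixtureSpec(seed=5, experiment_profile=profile))
        record = store.experiments[experiment_id]
        g = experiment_to_rdf(record)
        counts = {}
        for _, p, _ in g.triples():
            counts[str(p).rsplit("#", 1)[-1]] = counts.get(str(p).rsplit("#", 1)[-1], 0) + 1
        for name, count in expected_experiment_triples(record).items():
            assert counts.get(name, 0) == count, (profile, name)

    def test_export_is_deterministic_bytes(self):
        spec = FixtureSpec(seed=9)
        first = serialize_turtle(experiment_to_rdf(generate_store(spec)[0].experiments[f"exp-screen-9"]))
        second = serialize_turtle(experiment_to_rdf(generate_store(spec)[0].experiments[f"exp-screen-9"]))
        assert first == second

    def test_referential_closure(self, screen_store):
        g = screen_store.merged_graph("screen-1")
        subjects = {s for s, _, _ in g.triples()}
        from rdflib import URIRef

        for _, p, o in g.triples():
            if isinstance(o, URIRef) and p != RDF.type:
                assert o in subjects, f"dangling reference {o} via {p}"


class TestStepValidation:
    def test_unknown_plan_rejected(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        with pytest.raises(UnknownReference):
            store.add_step("e1", StepRecord("s1", "not-a-plan", "step"))

    def test_unknown_predecessor_rejected(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        with pytest.raises(UnknownReference):
            store.add_step("e1", StepRecord("s1", "e1", "step", predecessor="ghost"))

    def test_two_cycle_detected(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        store.add_step("e1", StepRecord("a", "e1", "first"))
        store.add_step("e1", StepRecord("b", "e1", "second", predecessor="a"))
        with pytest.raises(CycleDetected):
            store.set_predecessor("e1", "a", "b")

    def test_self_cycle_detected(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        store.add_step("e1", StepRecord("a", "e1", "first"))
        with pytest.raises(CycleDetected):
            store.set_predecessor("e1", "a", "a")


class TestAttachNotebook:
    def test_empty_plus_empty_is_union_plus_one_link(self):
        store = fresh_store()
        record = store.create_experiment("e1", "", T0)
        nb_graph = notebook_to_rdf(generate_notebook(FixtureSpec(seed=1, n_cells=0)))
        merged = attach_notebook_provenance(record, nb_graph)
        exp_graph = experiment_to_rdf(record)
        assert len(merged) == len(exp_graph) + len(nb_graph) + 1
        assert nb_graph.triples() <= merged.triples()
        links = [t for t in merged.triples() if t[1] == PPLAN.isSubPlanOfPlan]
        assert len(links) == 1

    def test_attach_is_idempotent(self):
        store = fresh_store()
        record = store.create_experiment("e1", "", T0)
        nb_graph = notebook_to_rdf(generate_notebook(FixtureSpec(seed=2, n_cells=1, runs_per_cell=1)))
        once = attach_notebook_provenance(record, nb_graph)
        twice = attach_notebook_provenance(record, nb_graph, merged=once)
        assert once == twice

    def test_graph_without_notebook_node_rejected(self):
        store = fresh_store()
        record = store.create_experiment("e1", "", T0)
        with pytest.raises(NotAProvlinkGraph):
            attach_notebook_provenance(record, ProvGraphDoc())


class TestVersioning:
    def test_history_grows_by_one_per_mutation(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        assert len(store.version_history("e1")) == 1
        store.add_dataset("e1", DatasetRef("d1", "set"))
        store.set_title("e1", "new title")
        store.add_step("e1", StepRecord("s1", "e1", "step"))
        assert len(store.version_history("e1")) == 4
        assert [v.version for v in store.version_history("e1")] == [1, 2, 3, 4]

    def test_saved_at_strictly_increasing(self):
        store = ExperimentStore(clock=lambda: T0)  # a stalled clock
        store.create_experiment("e1", "t", T0)
        store.set_title("e1", "a")
        store.set_title("e1", "b")
        times = [v.saved_at for v in store.version_history("e1")]
        assert times == sorted(times) and len(set(times)) == 3

    def test_compare_version_with_itself_is_empty(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        assert store.compare_versions("e1", 1, 1) == []

    def test_title_edit_yields_exactly_one_change_path(self):
        store = fresh_store()
        store.create_experiment("e1", "old title", T0)
        store.set_title("e1", "new title")
        changes = store.compare_versions("e1", 1, 2)
        assert len(changes) == 1
        assert changes[0] == {"path": "title", "kind": "changed", "old": "old title", "new": "new title"}

    def test_snapshots_are_immutable(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        old = store.version_history("e1")[0].content
        store.set_title("e1", "changed")
        store.add_dataset("e1", DatasetRef("d1", "set"))
        assert store.version_history("e1")[0].content == old
        assert old["title"] == "t" and old["datasets"] == []

    def test_unknown_version_rejected(self):
        store = fresh_store()
        store.create_experiment("e1", "t", T0)
        with pytest.raises(UnknownVersion):
            store.compare_versions("e1", 1, 99)


def test_store_json_round_trip(linked_store):
    store, experiment_id, notebook_id = linked_store
    text = store.to_json()
    again = ExperimentStore.from_json(text)
    assert again.to_json() == text
    assert again.experiments[experiment_id] == store.experiments[experiment_id]
    assert serialize_turtle(again.merged_graph(experiment_id)) == serialize_turtle(store.merged_graph(experiment_id))
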