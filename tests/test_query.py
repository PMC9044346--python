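"""Competency queries against nested-loop oracles, and the ProvTrack view."""

import pytest
from rdflib.namespace import RDF

from provlink import (
    FixtureSpec,
    build_provtrack_view,
    complete_path_experiment,
    complete_path_notebook,
    generate_linked_store,
    generate_notebook,
    notebook_to_rdf,
    path_to_root,
    run_select,
    search_view,
)
from provlink.errors import QuerySyntaxError, UnknownNode, UnsupportedFeature
from provlink.fixtures import generate_store
from provlink.notebook import Notebook
from provlink.rdf import ProvGraphDoc, mint
from provlink.query import LISTING_2
from provlink.vocab import REPR

from oracles import oracle_listing1_rows, oracle_listing2_rows, reachable_individuals


class TestRunSelect:
    def test_empty_graph_yields_no_rows(self):
        table = run_select(ProvGraphDoc(), "SELECT ?s WHERE { ?s a repr:Notebook }")
        assert len(table) == 0

    def test_single_notebook_matches_once(self):
        g = notebook_to_rdf(Notebook(stable_id="n1"))
        table = run_select(g, "SELECT ?s WHERE { ?s a repr:Notebook }")
        assert len(table) == 1

    def test_listing2_verbatim_matches_oracle_join(self, linked_store):
        import oracles

        store, _, notebook_id = linked_store
        nb = store.notebook(notebook_id)
        table = run_select(notebook_to_rdf(nb, store.base), LISTING_2)
        got = {tuple(row[v] for v in oracles.LISTING_2_VARS) for row in table.rows}
        assert got == oracle_listing2_rows(nb, store.base)

    def test_syntax_error_raised(self):
        with pytest.raises(QuerySyntaxError):
            run_select(ProvGraphDoc(), "SELECT WHERE {")

    def test_unsupported_feature_raised(self):
        with pytest.raises(UnsupportedFeature):
            run_select(ProvGraphDoc(), "SELECT ?s WHERE { SERVICE <http://x.org/sparql> { ?s ?p ?o } }")


def _as_variable_order(table, rows):
    """Project oracle rows (fixed tuple order) onto the table's variable order."""
    return rows


class TestCompetencyQueries:
    @pytest.mark.parametrize("seed", range(6))
    def test_listing2_rows_equal_oracle(self, seed):
        spec = FixtureSpec(seed=seed, n_cells=seed % 6, runs_per_cell=1 + seed % 3,
                           experiment_profile=["cpcf", "palm_dstorm", "screen"][seed % 3])
        store, _, notebook_id = generate_linked_store(spec)
        table = complete_path_notebook(store, notebook_id)
        expected = oracle_listing2_rows(store.notebook(notebook_id), store.base)
        got = {
            tuple(row[v] for v in ["step", "notebook", "execution", "executionTime", "inputVar", "outputVar", "previousStep"])
            for row in table.rows
        }
        assert got == expected

    def test_three_cells_two_runs_yield_four_rows(self):
        store, _, notebook_id = generate_linked_store(FixtureSpec(seed=1, n_cells=3, runs_per_cell=2))
        assert len(complete_path_notebook(store, notebook_id)) == 4

    def test_single_cell_notebook_yields_no_rows(self):
        store, _, notebook_id = generate_linked_store(FixtureSpec(seed=2, n_cells=1, runs_per_cell=2))
        assert len(complete_path_notebook(store, notebook_id)) == 0

    def test_execution_time_column_equals_stored_elapsed(self, linked_store):
        store, _, notebook_id = linked_store
        nb = store.notebook(notebook_id)
        stored = {str(r.elapsed_ms) for c in nb.code_cells() for r in c.executions}
        table = complete_path_notebook(store, notebook_id)
        assert {row["executionTime"] for row in table.rows} <= stored

    @pytest.mark.parametrize("seed", range(4))
    def test_listing1_rows_equal_oracle(self, seed):
        spec = FixtureSpec(seed=seed, n_cells=1 + seed % 3, runs_per_cell=1,
                           experiment_profile=["cpcf", "palm_dstorm", "screen"][seed % 3])
        store, experiment_id, _ = generate_linked_store(spec)
        table = complete_path_experiment(store, experiment_id)
        import oracles

        got = {tuple(row[v] for v in oracles.LISTING_1_VARS) for row in table.rows}
        assert got == oracle_listing1_rows(store, experiment_id)

    def test_instrument_free_experiment_returns_no_rows(self):
        # incomplete metadata: a mandatory pattern fails, the query "returns null"
        store, experiment_id = generate_store(FixtureSpec(seed=3, experiment_profile="minimal"))
        assert len(complete_path_experiment(store, experiment_id)) == 0

    def test_step_with_input_and_output_contributes_two_union_rows(self):
        # per context (agent x image x instrument setting x plan variable),
        # a step with one input and one output lands in both UNION branches
        store, experiment_id = generate_store(FixtureSpec(seed=4, experiment_profile="screen"))
        table = complete_path_experiment(store, experiment_id)
        record = store.experiments[experiment_id]
        step = next(s for s in record.steps if s.plan_id == experiment_id)
        assert len(step.inputs) == 1 and len(step.outputs) == 1
        step_iri = str(mint(store.base, "step", step.id))
        step_rows = [row for row in table.rows if row["step"] == step_iri]
        input_rows = [row for row in step_rows if row["Input"] is not None]
        output_rows = [row for row in step_rows if row["Output"] is not None]
        assert len(input_rows) == len(output_rows) > 0
        assert len(step_rows) == 2 * len(input_rows)


class TestProvTrackView:
    def test_minimal_experiment_is_single_plan_root(self):
        store, experiment_id = generate_store(FixtureSpec(seed=1, experiment_profile="minimal"))
        view = build_provtrack_view(store, experiment_id)
        assert len(view.nodes) == 1
        root = view.nodes[view.root]
        assert root.node_type == "Plan" and root.parent is None

    def test_node_type_multiset_matches_oracle_counts(self, linked_store):
        store, experiment_id, notebook_id = linked_store
        view = build_provtrack_view(store, experiment_id)
        record = store.experiments[experiment_id]
        nb = store.notebook(notebook_id)
        by_type = {}
        for node in view.nodes.values():
            by_type[node.node_type] = by_type.get(node.node_type, 0) + 1
        assert by_type["Agent"] == len(record.agents)
        assert by_type["Step"] == len(record.steps) + len(nb.code_cells())
        assert by_type["Plan"] == 1 + len(record.subplans) + 1  # experiment + SOPs + notebook
        assert by_type["Activity"] == sum(len(c.executions) for c in nb.code_cells())
        n_vars = sum(len(s.inputs) + len(s.outputs) for s in record.steps) + 2 * len(nb.code_cells())
        assert by_type["Variable"] == n_vars

    def test_every_graph_individual_is_exactly_one_node(self, linked_store):
        store, experiment_id, _ = linked_store
        graph = store.merged_graph(experiment_id)
        view = build_provtrack_view(store, experiment_id)
        expected = reachable_individuals(graph, mint(store.base, "experiment", experiment_id))
        assert set(view.nodes) == expected
        assert len(view.nodes) == len(expected)

    def test_split_queries_equal_monolithic_traversal(self, linked_store):
        store, experiment_id, _ = linked_store
        graph = store.merged_graph(experiment_id)
        view = build_provtrack_view(store, experiment_id)
        assert set(view.nodes) == reachable_individuals(graph, mint(store.base, "experiment", experiment_id))

    def test_path_to_root_of_root(self, linked_store):
        store, experiment_id, _ = linked_store
        view = build_provtrack_view(store, experiment_id)
        assert path_to_root(view, view.root) == [view.root]

    def test_setting_path_walks_containment(self, linked_store):
        store, experiment_id, _ = linked_store
        view = build_provtrack_view(store, experiment_id)
        setting = next(i for i in view.nodes if "/setting/part-" in i)
        kinds = [view.nodes[i].id.split("/")[-2] if "/" in view.nodes[i].id else "" for i in path_to_root(view, setting)]
        assert kinds[0] != "" and path_to_root(view, setting)[-1] == view.root
        labels = [view.nodes[i].id for i in path_to_root(view, setting)]
        assert "/part/" in labels[1] and "/instrument/" in labels[2] and "/experiment/" in labels[3]

    def test_every_path_ends_at_root(self, linked_store):
        store, experiment_id, _ = linked_store
        view = build_provtrack_view(store, experiment_id)
        for node_id in view.nodes:
            assert path_to_root(view, node_id)[-1] == view.root

    def test_unknown_node_rejected(self, linked_store):
        store, experiment_id, _ = linked_store
        view = build_provtrack_view(store, experiment_id)
        with pytest.raises(UnknownNode):
            path_to_root(view, "nope")

    def test_view_serialization_is_deterministic(self, spec):
        first = build_provtrack_view(*generate_linked_store(spec)[:2])
        second = build_provtrack_view(*generate_linked_store(spec)[:2])
        assert first.to_json() == second.to_json()

    def test_infobox_properties_are_sorted_key_value_pairs(self, linked_store):
        store, experiment_id, _ = linked_store
        view = build_provtrack_view(store, experiment_id)
        for node in view.nodes.values():
            keys = [k for k, _ in node.properties]
            assert keys == sorted(keys)


class TestSearchView:
    @pytest.fixture
    def view(self, linked_store):
        store, experiment_id, _ = linked_store
        return build_provtrack_view(store, experiment_id)

    def test_empty_term_matches_everything_in_scope(self, view):
        assert search_view(view, "", scope="nodes") == list(view.nodes)
        assert search_view(view, "", scope="edges") == view.edges

    def test_edge_search_counts_hassetting_edges(self, view, linked_store):
        store, experiment_id, _ = linked_store
        graph = store.merged_graph(experiment_id)
        expected = sum(1 for _, p, _ in graph.triples() if p == REPR.hasSetting)
        matches = search_view(view, "hasSetting", scope="edges")
        assert len(matches) == expected > 0

    def test_absent_term_matches_nothing(self, view):
        assert search_view(view, "zzz-not-there", scope="nodes") == []

    def test_node_search_is_case_insensitive_substring(self, view):
        assert search_view(view, "CONFOCAL", scope="nodes") == search_view(view, "confocal", scope="nodes") != []
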