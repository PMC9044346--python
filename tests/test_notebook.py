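"""Notebook documents and execution-provenance capture."""

import json
from datetime import datetime, timedelta, timezone

import pytest

from provlink import (
    Cell,
    FixtureSpec,
    MockClock,
    MockExecutor,
    Notebook,
    clear_provenance,
    execute_and_capture,
    generate_notebook,
    humanize_duration,
    list_executions,
    read_notebook,
    record_execution,
    write_notebook,
)
from provlink.errors import NegativeDuration, NotACodeCell, SchemaError, UnknownCell
from provlink.fixtures import generate_unexecuted_notebook
from provlink.notebook import ALL, text_output

T0 = datetime(2021, 6, 1, 12, 0, 0, tzinfo=timezone.utc)


class TestReadWrite:
    def test_minimal_document_has_no_cells(self):
        nb = read_notebook('{"cells": [], "metadata": {}}')
        assert nb.cells == []

    @pytest.mark.parametrize("document", [
        '{"metadata": {}}',
        '{"cells": []}',
        '{"cells": {}, "metadata": {}}',
        '{"cells": [], "metadata": 3}',
        "not json at all",
    ])
    def test_malformed_documents_rejected(self, document):
        with pytest.raises(SchemaError):
            read_notebook(document)

    def test_empty_notebook_writes_empty_cells_list(self):
        doc = json.loads(write_notebook(Notebook()))
        assert doc["cells"] == [] and "metadata" in doc

    def test_hand_built_fixture_loads_provenance_sorted(self):
        # records stored out of order in the raw JSON come back sorted
        records = [
            {"start_time": f"2021-06-01T12:00:0{i}.000Z", "end_time": f"2021-06-01T12:00:0{i}.500Z",
             "elapsed_ms": 500, "source": "a = 1", "outputs": [], "environment_ref": None, "sequence_index": 0}
            for i in (2, 0, 1)
        ]
        doc = {
            "cells": [
                {"cell_type": "code", "source": "a = 1", "outputs": [], "execution_count": None,
                 "metadata": {"provenance": {"schema": 1, "records": records}}},
                {"cell_type": "code", "source": "b = 2", "outputs": [], "execution_count": None, "metadata": {}},
            ],
            "metadata": {},
        }
        nb = read_notebook(json.dumps(doc))
        runs = list_executions(nb.cells[0])
        assert len(runs) == 3
        assert [r.start_time.second for r in runs] == [0, 1, 2]
        assert runs[-1].start_time == max(r.start_time for r in runs)
        assert list_executions(nb.cells[1]) == []

    @pytest.mark.parametrize("seed,cells,runs", [(0, 0, 0), (1, 1, 1), (2, 3, 2), (3, 5, 3)])
    def test_round_trip_identity(self, seed, cells, runs):
        nb = generate_notebook(FixtureSpec(seed=seed, n_cells=cells, runs_per_cell=runs))
        assert read_notebook(write_notebook(nb)) == nb

    def test_unknown_metadata_keys_survive_round_trip(self, nb):
        nb.notebook_metadata["custom_tool"] = {"nested": [1, 2]}
        nb.cells[1].cell_metadata["tags"] = ["slow"]
        nb.extra["vendor_extension"] = True
        again = read_notebook(write_notebook(nb))
        assert again.notebook_metadata["custom_tool"] == {"nested": [1, 2]}
        assert again.cells[1].cell_metadata["tags"] == ["slow"]
        assert again.extra["vendor_extension"] is True

    def test_provenance_lives_under_documented_cell_metadata_key(self, nb):
        doc = json.loads(write_notebook(nb))
        code = [c for c in doc["cells"] if c["cell_type"] == "code"]
        for cell in code:
            block = cell["metadata"]["provenance"]
            assert block["schema"] == 1
            for record in block["records"]:
                assert set(record) == {"start_time", "end_time", "elapsed_ms", "source",
                                       "outputs", "environment_ref", "sequence_index"}


class TestRecordExecution:
    def test_zero_duration(self):
        cell = Cell(cell_type="code", source="pass")
        record = record_execution(cell, T0, T0, "pass", [])
        assert record.elapsed_ms == 0

    def test_elapsed_is_timestamp_arithmetic(self):
        cell = Cell(cell_type="code", source="pass")
        record = record_execution(cell, T0, T0 + timedelta(milliseconds=2500), "pass", [])
        assert record.elapsed_ms == 2500

    def test_identical_starts_get_increasing_sequence_index(self):
        cell = Cell(cell_type="code", source="pass")
        first = record_execution(cell, T0, T0, "pass", [])
        second = record_execution(cell, T0, T0, "pass", [])
        assert (first.sequence_index, second.sequence_index) == (0, 1)
        assert [r.sequence_index for r in list_executions(cell)] == [0, 1]

    def test_earlier_records_are_immutable_under_append(self):
        cell = Cell(cell_type="code", source="pass")
        for k in range(4):
            before = [json.dumps(r.to_json()) for r in list_executions(cell)]
            record_execution(cell, T0 + timedelta(seconds=k), T0 + timedelta(seconds=k), "pass", [])
            after = [json.dumps(r.to_json()) for r in list_executions(cell)]
            assert after[: len(before)] == before
            assert len(after) == k + 1

    def test_markdown_cell_refuses_records(self):
        with pytest.raises(NotACodeCell):
            record_execution(Cell(cell_type="markdown"), T0, T0, "", [])

    def test_negative_duration_rejected(self):
        with pytest.raises(NegativeDuration):
            record_execution(Cell(cell_type="code"), T0, T0 - timedelta(seconds=1), "", [])


class TestExecuteAndCapture:
    def test_markdown_only_notebook_gets_stamp_but_no_records(self):
        nb = Notebook(cells=[Cell(cell_type="markdown", source="# hi")])
        execute_and_capture(nb, MockExecutor(default=[]), MockClock())
        assert nb.environment is not None
        assert all(c.executions == [] for c in nb.cells)

    def test_each_run_adds_exactly_one_record_per_code_cell(self):
        spec = FixtureSpec(seed=5, n_cells=2, runs_per_cell=0)
        nb, executor, clock = generate_unexecuted_notebook(spec)
        execute_and_capture(nb, executor, clock)
        assert [len(c.executions) for c in nb.code_cells()] == [1, 1]
        first_round = [json.dumps(c.executions[0].to_json()) for c in nb.code_cells()]
        execute_and_capture(nb, executor, clock)
        assert [len(c.executions) for c in nb.code_cells()] == [2, 2]
        assert [json.dumps(c.executions[0].to_json()) for c in nb.code_cells()] == first_round

    def test_start_times_strictly_increase_in_document_order(self):
        nb = generate_notebook(FixtureSpec(seed=7, n_cells=4, runs_per_cell=1))
        starts = [c.executions[0].start_time for c in nb.code_cells()]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)

    def test_capture_pipeline_is_byte_deterministic(self):
        docs = {write_notebook(generate_notebook(FixtureSpec(seed=11))) for _ in range(3)}
        assert len(docs) == 1

    def test_executor_failure_recorded_not_raised(self):
        nb = Notebook(cells=[Cell(cell_type="code", source="boom"), Cell(cell_type="code", source="ok")])
        execute_and_capture(nb, MockExecutor(table={"ok": [text_output("fine")]}), MockClock())
        assert nb.cells[0].executions[0].outputs_snapshot[0].output_kind == "error"
        assert nb.cells[1].outputs[0].mime_bundle["text/plain"] == "fine"


class TestClearProvenance:
    def test_clear_all_on_clean_notebook_is_noop(self):
        nb = Notebook(cells=[Cell(cell_type="code", source="a")])
        before = write_notebook(nb)
        assert write_notebook(clear_provenance(nb, ALL)) == before

    def test_clear_single_cell_leaves_others(self, nb):
        target, other = nb.code_cells()[0], nb.code_cells()[1]
        clear_provenance(nb, target.stable_id)
        assert target.executions == [] and len(other.executions) == 2

    def test_clear_all_then_write_has_no_provenance_keys(self, nb):
        doc = json.loads(write_notebook(clear_provenance(nb, ALL)))
        assert not any("provenance" in c["metadata"] for c in doc["cells"])

    def test_unknown_cell_selector(self, nb):
        with pytest.raises(UnknownCell):
            clear_provenance(nb, "no-such-cell")


class TestHumanizeDuration:
    @pytest.mark.parametrize("ms,text", [
        (0, "0ms"),
        (41, "41ms"),
        (41.3, "41.3ms"),
        (999, "999ms"),
        (1000, "1s"),
        (2500, "2.5s"),
        (59_940, "59.9s"),
        (155_000, "2 min 35s"),
        (235_000, "3 min 55s"),
        (3_600_000, "1 h 0 min 0s"),
    ])
    def test_mapping(self, ms, text):
        assert humanize_duration(ms) == text

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            humanize_duration(-1)


def test_document_size_grows_monotonically_with_records():
    sizes = [
        len(write_notebook(generate_notebook(FixtureSpec(seed=1, n_cells=2, runs_per_cell=r))))
        for r in range(4)
    ]
    assert sizes == sorted(sizes) and sizes[0] < sizes[-1]
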