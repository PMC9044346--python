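"""Notebook documents and per-cell execution provenance.

A computational notebook is an ipynb JSON document (nbformat-4 schema) whose
top level carries the keys ``"metadata"`` and ``"cells"``.  This module reads
and writes such documents with the standard library ``json`` module and adds
an execution-provenance layer: every run of a code cell is recorded as an
:class:`ExecutionRecord` (start time, end time, elapsed duration, a snapshot
of the source and of the outputs, and a reference to the execution
environment) stored under a single well-known key in the cell's metadata.
Documents written here remain valid notebooks for any standard reader —
provenance is ordinary cell metadata.

Provenance schema (version 1)::

    cell.metadata["provenance"] = {
        "schema": 1,
        "records": [
            {"start_time": "...Z", "end_time": "...Z", "elapsed_ms": 2500,
             "source": "...", "outputs": [...], "environment_ref": "env-...",
             "sequence_index": 0},
            ...
        ],
    }

    notebook.metadata["provenance_environment"] = {os/language/packages ...}

Timestamps are ISO-8601 UTC with millisecond precision so that lexicographic
ordering equals temporal ordering.  Records are kept sorted ascending by
``(start_time, sequence_index)``; the sequence index is assigned at append
time and breaks ties between runs that share a start timestamp.
"""

from __future__ import annotations

import base64
import binascii
import contextlib
import hashlib
import io
import json
import platform
import sys
import traceback as _traceback
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from numbers import Real
from typing import Iterable, Protocol

from .errors import (
    ExecutorFailure,
    NegativeDuration,
    NotACodeCell,
    ProvenanceSchemaError,
    SchemaError,
    UnknownCell,
)

PROVENANCE_KEY = "provenance"
PROVENANCE_SCHEMA_VERSION = 1
ENVIRONMENT_KEY = "provenance_environment"
STABLE_ID_KEY = "provlink_id"

#: Selector accepted by :func:`clear_provenance` meaning "every code cell".
ALL = "__all__"

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


# --------------------------------------------------------------------------
# timestamps

def format_timestamp(ts: datetime) -> str:
    """Render a UTC timestamp as ISO-8601 with millisecond precision."""
    ts = to_utc_ms(ts)
    return ts.strftime(_TS_FORMAT)[:-3] + "Z"


def parse_timestamp(text: str) -> datetime:
    if text.endswith("Z"):
        text = text[:-1] + "+00:00"
    ts = datetime.fromisoformat(text)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return to_utc_ms(ts)


def to_utc_ms(ts: datetime) -> datetime:
    """Convert to UTC and truncate to whole milliseconds."""
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    ts = ts.astimezone(timezone.utc)
    return ts.replace(microsecond=(ts.microsecond // 1000) * 1000)


# --------------------------------------------------------------------------
# outputs

_OUTPUT_KINDS = ("stream", "display_data", "execute_result", "error")


@dataclass
class CellOutput:
    """One output of a code-cell execution.

    ``mime_bundle`` maps a mime type to its content: unicode text for
    ``text/*`` and ``application/*`` entries, base64 text for ``image/*``
    entries.  Stream and error outputs use the dedicated fields instead.
    """

    output_kind: str
    mime_bundle: dict[str, str] = field(default_factory=dict)
    stream_name: str | None = None
    error_name: str | None = None
    error_value: str | None = None
    traceback: list[str] | None = None

    def __post_init__(self) -> None:
        if self.output_kind not in _OUTPUT_KINDS:
            raise SchemaError(f"unknown output kind: {self.output_kind!r}")
        for mime, content in self.mime_bundle.items():
            if mime.startswith("image/") and mime != "image/svg+xml":
                try:
                    base64.b64decode(content, validate=True)
                except (binascii.Error, ValueError) as exc:
                    raise SchemaError(f"invalid base64 for {mime}: {exc}") from exc

    def image_bytes(self, mime: str) -> bytes:
        return base64.b64decode(self.mime_bundle[mime])

    # nbformat-4 output objects
    def to_nb_json(self) -> dict:
        if self.output_kind == "stream":
            return {
                "output_type": "stream",
                "name": self.stream_name or "stdout",
                "text": self.mime_bundle.get("text/plain", ""),
            }
        if self.output_kind == "error":
            return {
                "output_type": "error",
                "ename": self.error_name or "",
                "evalue": self.error_value or "",
                "traceback": list(self.traceback or []),
            }
        out: dict = {
            "output_type": self.output_kind,
            "data": dict(sorted(self.mime_bundle.items())),
            "metadata": {},
        }
        if self.output_kind == "execute_result":
            out["execution_count"] = None
        return out

    @classmethod
    def from_nb_json(cls, obj: dict) -> "CellOutput":
        if not isinstance(obj, dict) or "output_type" not in obj:
            raise SchemaError(f"malformed output object: {obj!r}")
        kind = obj["output_type"]
        if kind == "stream":
            text = obj.get("text", "")
            if isinstance(text, list):
                text = "".join(text)
            return cls("stream", {"text/plain": text}, stream_name=obj.get("name", "stdout"))
        if kind == "error":
            return cls(
                "error",
                error_name=obj.get("ename", ""),
                error_value=obj.get("evalue", ""),
                traceback=list(obj.get("traceback", [])),
            )
        if kind in ("display_data", "execute_result"):
            data = {}
            for mime, content in obj.get("data", {}).items():
                if isinstance(content, list):
                    content = "".join(content)
                data[mime] = content
            return cls(kind, data)
        raise SchemaError(f"unknown output_type: {kind!r}")


def text_output(text: str, kind: str = "execute_result") -> CellOutput:
    return CellOutput(kind, {"text/plain": text})


def stream_output(text: str, name: str = "stdout") -> CellOutput:
    return CellOutput("stream", {"text/plain": text}, stream_name=name)


def image_output(png_bytes: bytes) -> CellOutput:
    return CellOutput("display_data", {"image/png": base64.b64encode(png_bytes).decode("ascii")})


def error_output(name: str, value: str, tb: list[str] | None = None) -> CellOutput:
    return CellOutput("error", error_name=name, error_value=value, traceback=tb or [f"{name}: {value}"])


# --------------------------------------------------------------------------
# execution environment

@dataclass
class ExecutionEnvironment:
    """The environment a notebook was executed in (OS, language, packages)."""

    os_name: str
    os_version: str
    language_name: str
    language_version: str
    packages: dict[str, str] = field(default_factory=dict)
    captured_at: datetime = field(default_factory=lambda: to_utc_ms(datetime.now(timezone.utc)))

    def __post_init__(self) -> None:
        self.captured_at = to_utc_ms(self.captured_at)

    @property
    def ref(self) -> str:
        """A stable content-derived identifier for this environment."""
        payload = json.dumps(self.to_json(), sort_keys=True).encode()
        return "env-" + hashlib.sha1(payload).hexdigest()[:12]

    def to_json(self) -> dict:
        return {
            "os_name": self.os_name,
            "os_version": self.os_version,
            "language_name": self.language_name,
            "language_version": self.language_version,
            "packages": dict(sorted(self.packages.items())),
            "captured_at": format_timestamp(self.captured_at),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ExecutionEnvironment":
        return cls(
            os_name=obj["os_name"],
            os_version=obj["os_version"],
            language_name=obj["language_name"],
            language_version=obj["language_version"],
            packages=dict(obj.get("packages", {})),
            captured_at=parse_timestamp(obj["captured_at"]),
        )

    @classmethod
    def capture_current(cls, packages: dict[str, str] | None = None) -> "ExecutionEnvironment":
        return cls(
            os_name=platform.system(),
            os_version=platform.release(),
            language_name="python",
            language_version=platform.python_version(),
            packages=packages or {},
        )


# --------------------------------------------------------------------------
# execution records

@dataclass
class ExecutionRecord:
    """One run of one code cell.

    ``elapsed_ms`` is always exactly ``end_time - start_time`` in integer
    milliseconds; ``sequence_index`` breaks ties between records sharing a
    start timestamp, making ``(start_time, sequence_index)`` unique within a
    cell.
    """

    start_time: datetime
    end_time: datetime
    elapsed_ms: int
    source_snapshot: str
    outputs_snapshot: list[CellOutput] = field(default_factory=list)
    environment_ref: str | None = None
    sequence_index: int = 0

    def __post_init__(self) -> None:
        self.start_time = to_utc_ms(self.start_time)
        self.end_time = to_utc_ms(self.end_time)
        if self.end_time < self.start_time:
            raise NegativeDuration(
                f"end {format_timestamp(self.end_time)} precedes start {format_timestamp(self.start_time)}"
            )
        expected = round((self.end_time - self.start_time).total_seconds() * 1000)
        if self.elapsed_ms != expected:
            raise ProvenanceSchemaError(
                f"elapsed_ms {self.elapsed_ms} != end-start {expected}"
            )

    @property
    def sort_key(self) -> tuple[str, int]:
        return (format_timestamp(self.start_time), self.sequence_index)

    def to_json(self) -> dict:
        return {
            "start_time": format_timestamp(self.start_time),
            "end_time": format_timestamp(self.end_time),
            "elapsed_ms": self.elapsed_ms,
            "source": self.source_snapshot,
            "outputs": [o.to_nb_json() for o in self.outputs_snapshot],
            "environment_ref": self.environment_ref,
            "sequence_index": self.sequence_index,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ExecutionRecord":
        try:
            return cls(
                start_time=parse_timestamp(obj["start_time"]),
                end_time=parse_timestamp(obj["end_time"]),
                elapsed_ms=int(obj["elapsed_ms"]),
                source_snapshot=obj["source"],
                outputs_snapshot=[CellOutput.from_nb_json(o) for o in obj.get("outputs", [])],
                environment_ref=obj.get("environment_ref"),
                sequence_index=int(obj.get("sequence_index", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ProvenanceSchemaError(f"malformed execution record: {exc}") from exc


# --------------------------------------------------------------------------
# cells and notebooks

_CELL_TYPES = ("code", "markdown", "raw")


@dataclass
class Cell:
    cell_type: str
    source: str = ""
    cell_metadata: dict = field(default_factory=dict)
    outputs: list[CellOutput] = field(default_factory=list)
    execution_count: int | None = None
    stable_id: str | None = None
    executions: list[ExecutionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_type not in _CELL_TYPES:
            raise SchemaError(f"unknown cell type: {self.cell_type!r}")
        if self.executions and self.cell_type != "code":
            raise ProvenanceSchemaError("provenance records exist only on code cells")
        self._validate_records(self.executions)
        self.executions.sort(key=lambda r: r.sort_key)

    @staticmethod
    def _validate_records(records: Iterable[ExecutionRecord]) -> None:
        seen = set()
        for r in records:
            if r.sort_key in seen:
                raise ProvenanceSchemaError(
                    f"duplicate (start_time, sequence_index) {r.sort_key}"
                )
            seen.add(r.sort_key)


@dataclass
class Notebook:
    notebook_metadata: dict = field(default_factory=dict)
    cells: list[Cell] = field(default_factory=list)
    stable_id: str | None = None
    environment: ExecutionEnvironment | None = None
    nbformat: int = 4
    nbformat_minor: int = 5
    extra: dict = field(default_factory=dict)

    def code_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.cell_type == "code"]

    def cell_by_id(self, stable_id: str) -> Cell:
        for c in self.cells:
            if c.stable_id == stable_id:
                return c
        raise UnknownCell(f"no cell with id {stable_id!r}")


def ensure_stable_ids(nb: Notebook) -> Notebook:
    """Mint missing stable identifiers (random UUIDs) in place."""
    if nb.stable_id is None:
        nb.stable_id = str(uuid.uuid4())
    for cell in nb.cells:
        if cell.stable_id is None:
            cell.stable_id = str(uuid.uuid4())
    return nb


# --------------------------------------------------------------------------
# document read/write

def read_notebook(document_text: str) -> Notebook:
    """Parse an ipynb JSON document, loading any stored provenance.

    Raises :class:`SchemaError` when the top-level ``"cells"`` or
    ``"metadata"`` key is absent or of the wrong shape, and
    :class:`ProvenanceSchemaError` when a stored provenance record violates
    the execution-record invariants.  Unknown keys are retained.
    """
    try:
        doc = json.loads(document_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("notebook document must be a JSON object")
    if "cells" not in doc or not isinstance(doc["cells"], list):
        raise SchemaError('notebook document must carry a "cells" list')
    if "metadata" not in doc or not isinstance(doc["metadata"], dict):
        raise SchemaError('notebook document must carry a "metadata" object')

    metadata = dict(doc["metadata"])
    stable_id = metadata.pop(STABLE_ID_KEY, None)
    environment = None
    if ENVIRONMENT_KEY in metadata:
        environment = ExecutionEnvironment.from_json(metadata.pop(ENVIRONMENT_KEY))

    cells = [_read_cell(c) for c in doc["cells"]]
    extra = {k: v for k, v in doc.items() if k not in ("cells", "metadata", "nbformat", "nbformat_minor")}
    return Notebook(
        notebook_metadata=metadata,
        cells=cells,
        stable_id=stable_id,
        environment=environment,
        nbformat=doc.get("nbformat", 4),
        nbformat_minor=doc.get("nbformat_minor", 5),
        extra=extra,
    )


def _read_cell(obj: dict) -> Cell:
    if not isinstance(obj, dict) or "cell_type" not in obj:
        raise SchemaError(f"malformed cell: {obj!r}")
    source = obj.get("source", "")
    if isinstance(source, list):
        source = "".join(source)
    metadata = dict(obj.get("metadata", {}))
    stable_id = metadata.pop(STABLE_ID_KEY, None)
    executions: list[ExecutionRecord] = []
    if PROVENANCE_KEY in metadata:
        block = metadata.pop(PROVENANCE_KEY)
        if not isinstance(block, dict) or "records" not in block:
            raise ProvenanceSchemaError(f"malformed provenance block: {block!r}")
        executions = [ExecutionRecord.from_json(r) for r in block["records"]]
        if obj["cell_type"] != "code":
            raise ProvenanceSchemaError("provenance records exist only on code cells")
    outputs = [CellOutput.from_nb_json(o) for o in obj.get("outputs", [])] if obj["cell_type"] == "code" else []
    return Cell(
        cell_type=obj["cell_type"],
        source=source,
        cell_metadata=metadata,
        outputs=outputs,
        execution_count=obj.get("execution_count"),
        stable_id=stable_id,
        executions=executions,
    )


def write_notebook(nb: Notebook) -> str:
    """Serialize a notebook back to ipynb JSON text.

    ``read_notebook(write_notebook(nb)) == nb`` for any valid notebook; the
    serialization itself is deterministic (sorted keys, fixed indentation).
    """
    cells = []
    for cell in nb.cells:
        metadata = dict(cell.cell_metadata)
        if cell.stable_id is not None:
            metadata[STABLE_ID_KEY] = cell.stable_id
        if cell.executions:
            metadata[PROVENANCE_KEY] = {
                "schema": PROVENANCE_SCHEMA_VERSION,
                "records": [r.to_json() for r in sorted(cell.executions, key=lambda r: r.sort_key)],
            }
        obj: dict = {"cell_type": cell.cell_type, "metadata": metadata, "source": cell.source}
        if cell.cell_type == "code":
            obj["outputs"] = [o.to_nb_json() for o in cell.outputs]
            obj["execution_count"] = cell.execution_count
        cells.append(obj)
    metadata = dict(nb.notebook_metadata)
    if nb.stable_id is not None:
        metadata[STABLE_ID_KEY] = nb.stable_id
    if nb.environment is not None:
        metadata[ENVIRONMENT_KEY] = nb.environment.to_json()
    doc = {
        "cells": cells,
        "metadata": metadata,
        "nbformat": nb.nbformat,
        "nbformat_minor": nb.nbformat_minor,
        **nb.extra,
    }
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n"


# --------------------------------------------------------------------------
# provenance capture

def record_execution(
    cell: Cell,
    start: datetime,
    end: datetime,
    source: str,
    outputs: list[CellOutput],
    env_ref: str | None = None,
) -> ExecutionRecord:
    """Append a new execution record to a code cell.

    Previously stored records are untouched; the record list stays sorted by
    ``(start_time, sequence_index)`` with the sequence index assigned here.
    """
    if cell.cell_type != "code":
        raise NotACodeCell(f"cannot record execution on a {cell.cell_type} cell")
    start = to_utc_ms(start)
    end = to_utc_ms(end)
    if end < start:
        raise NegativeDuration(
            f"end {format_timestamp(end)} precedes start {format_timestamp(start)}"
        )
    same_start = [r.sequence_index for r in cell.executions if r.start_time == start]
    record = ExecutionRecord(
        start_time=start,
        end_time=end,
        elapsed_ms=round((end - start).total_seconds() * 1000),
        source_snapshot=source,
        outputs_snapshot=list(outputs),
        environment_ref=env_ref,
        sequence_index=max(same_start) + 1 if same_start else 0,
    )
    cell.executions.append(record)
    cell.executions.sort(key=lambda r: r.sort_key)
    return record


def list_executions(cell: Cell) -> list[ExecutionRecord]:
    """All stored runs of a cell, ascending by (start_time, sequence_index).

    The start and end times double as the execution order: the last element
    is the most recent run.  Markdown and raw cells yield an empty list.
    """
    return sorted(cell.executions, key=lambda r: r.sort_key)


def clear_provenance(nb: Notebook, selector: str) -> Notebook:
    """Drop provenance of one code cell (by stable id) or of all cells."""
    if selector == ALL:
        for cell in nb.cells:
            cell.executions = []
        return nb
    cell = nb.cell_by_id(selector)
    if cell.cell_type != "code":
        raise UnknownCell(f"cell {selector!r} is not a code cell")
    cell.executions = []
    return nb


# --------------------------------------------------------------------------
# executors and clocks

class Executor(Protocol):
    """Executes a cell source in some environment, yielding outputs."""

    environment: ExecutionEnvironment

    def execute(self, source: str) -> list[CellOutput]: ...


class MockExecutor:
    """Deterministic table-driven executor for tests and dry runs.

    Pure by construction: the same source always maps to the same outputs.
    Sources absent from the table raise :class:`ExecutorFailure` (which the
    capture loop records as an error output, mirroring notebook behaviour).
    """

    def __init__(
        self,
        table: dict[str, list[CellOutput]] | None = None,
        environment: ExecutionEnvironment | None = None,
        default: list[CellOutput] | None = None,
    ) -> None:
        self.table = dict(table or {})
        self.default = default
        self.environment = environment or ExecutionEnvironment(
            os_name="MockOS",
            os_version="1.0",
            language_name="python",
            language_version="3.11",
            packages={"provlink-mock": "1"},
            captured_at=datetime(2020, 1, 1, tzinfo=timezone.utc),
        )

    def execute(self, source: str) -> list[CellOutput]:
        if source in self.table:
            return list(self.table[source])
        if self.default is not None:
            return list(self.default)
        raise ExecutorFailure(f"no mock output defined for source {source!r}")


class KernelExecutor:
    """Headless in-process Python executor.

    Runs each code cell with ``exec`` in one shared namespace, capturing
    stdout as a stream output, the repr of a trailing expression as an
    execute_result, and exceptions as error outputs.  Suitable for simple
    whole-notebook runs without a separate kernel process.
    """

    def __init__(self, environment: ExecutionEnvironment | None = None) -> None:
        self.environment = environment or ExecutionEnvironment.capture_current()
        self.namespace: dict = {}

    def execute(self, source: str) -> list[CellOutput]:
        outputs: list[CellOutput] = []
        stdout = io.StringIO()
        try:
            body = compile(source, "<cell>", "exec")
            with contextlib.redirect_stdout(stdout):
                exec(body, self.namespace)
            # a trailing expression also yields its repr, like a notebook
            lines = source.rstrip().rsplit("\n", 1)
            last = lines[-1]
            try:
                value = eval(compile(last, "<cell>", "eval"), self.namespace)
                if value is not None:
                    outputs.append(text_output(repr(value)))
            except Exception:
                pass
        except Exception as exc:
            outputs.append(error_output(type(exc).__name__, str(exc), _traceback.format_exc().splitlines()))
        if stdout.getvalue():
            outputs.insert(0, stream_output(stdout.getvalue()))
        return outputs


class SystemClock:
    def now(self) -> datetime:
        return to_utc_ms(datetime.now(timezone.utc))


class MockClock:
    """Deterministic clock: starts at a fixed epoch and ticks on every read.

    The default epoch is 2020-01-01T00:00:00Z; each ``now()`` advances the
    clock by ``tick_ms`` before returning, so successive reads are strictly
    increasing.
    """

    EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)

    def __init__(self, epoch: datetime | None = None, tick_ms: int = 500) -> None:
        self.current = to_utc_ms(epoch or self.EPOCH)
        self.tick_ms = tick_ms

    def now(self) -> datetime:
        value = self.current
        self.current = self.current + timedelta(milliseconds=self.tick_ms)
        return value


def execute_and_capture(nb: Notebook, executor: Executor, clock=None) -> Notebook:
    """Run every code cell in document order, recording one execution each.

    Start times are strictly increasing in document order; each cell's
    outputs are replaced by the run's outputs; executor failures become
    error outputs rather than aborting the remaining cells.  The executor's
    environment is stamped on the notebook.
    """
    clock = clock or SystemClock()
    nb.environment = executor.environment
    env_ref = executor.environment.ref
    run_index = max((c.execution_count or 0) for c in nb.cells) + 1 if nb.cells else 1
    for cell in nb.cells:
        if cell.cell_type != "code":
            continue
        start = clock.now()
        try:
            outputs = executor.execute(cell.source)
        except ExecutorFailure as exc:
            outputs = [error_output("ExecutorFailure", str(exc))]
        end = clock.now()
        if end < start:  # guard against non-monotonic wall clocks
            end = start
        record_execution(cell, start, end, cell.source, outputs, env_ref)
        cell.outputs = list(outputs)
        cell.execution_count = run_index
    return nb


# --------------------------------------------------------------------------
# display

def humanize_duration(elapsed_ms: Real) -> str:
    """Render an elapsed duration the way a person reads it.

    Mapping (deterministic): below one second → milliseconds ("41.3ms",
    fractional part kept only when present); below one minute → seconds
    ("2.5s"); below one hour → "M min Ss"; one hour and up →
    "H h M min Ss".  Seconds inside minute/hour renderings are rounded to
    the nearest whole second.
    """
    if elapsed_ms < 0:
        raise ValueError("duration must be non-negative")
    if elapsed_ms < 1000:
        return f"{_trim(elapsed_ms)}ms"
    if elapsed_ms < 60_000:
        return f"{_trim(round(elapsed_ms / 1000, 1))}s"
    total_s = round(elapsed_ms / 1000)
    if total_s < 3600:
        return f"{total_s // 60} min {total_s % 60}s"
    return f"{total_s // 3600} h {(total_s % 3600) // 60} min {total_s % 60}s"


def _trim(x: Real) -> str:
    value = float(x)
    return str(int(value)) if value == int(value) else str(value)
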