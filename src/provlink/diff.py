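"""Content-based comparison of two executions of a code cell.

Two runs of a cell are selected by their start times and compared on both
sides of the execution: the source snapshots are diffed line by line with a
minimal (LCS) edit script, and the output snapshots are paired positionally
within their content kind and compared by content — text outputs line by
line, image outputs by decoded byte equality.

The rendered diff marks deletions and insertions the way review tools
colour them: ``-``/``+`` prefixes in plain style, ``[-...-]`` / ``{+...+}``
wrappers (the red/green roles) in marked style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmbiguousExecution, NoSuchExecution
from .notebook import (
    Cell,
    CellOutput,
    ExecutionRecord,
    format_timestamp,
    list_executions,
    parse_timestamp,
    to_utc_ms,
)


# --------------------------------------------------------------------------
# edit scripts

@dataclass
class SourceEdit:
    """One segment of a line-based edit script.

    Line ranges are 0-based and half-open; ``equal`` segments cover both
    sides, ``delete`` only the left, ``insert`` only the right.
    """

    op: str  # equal | delete | insert
    left_lines: tuple[int, int]
    right_lines: tuple[int, int]
    text: list[str] = field(default_factory=list)


def _split_lines(source: str) -> list[str]:
    return source.split("\n") if source else []


def line_diff(left: str, right: str) -> list[SourceEdit]:
    """Minimal line-based edit script turning ``left`` into ``right``.

    Classic LCS dynamic program with backtrack; segments are grouped so the
    script alternates maximal equal/delete/insert runs, deletions emitted
    before insertions at each divergence.
    """
    a, b = _split_lines(left), _split_lines(right)
    n, m = len(a), len(b)
    # lcs[i][j] = LCS length of a[i:], b[j:]
    lcs = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = lcs[i], lcs[i + 1]
        for j in range(m - 1, -1, -1):
            row[j] = nxt[j + 1] + 1 if a[i] == b[j] else max(nxt[j], row[j + 1])

    ops: list[tuple[str, int, int]] = []  # (op, left index, right index)
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            ops.append(("equal", i, j))
            i += 1
            j += 1
            continue
        left_skip, right_skip = lcs[i + 1][j], lcs[i][j + 1]
        # tie-break by line content: self-dual, so diff(a, b) and diff(b, a)
        # are exact mirrors even when several minimal scripts exist
        if left_skip > right_skip or (left_skip == right_skip and a[i] < b[j]):
            ops.append(("delete", i, j))
            i += 1
        else:
            ops.append(("insert", i, j))
            j += 1
    ops.extend(("delete", k, j) for k in range(i, n))
    ops.extend(("insert", n, k) for k in range(j, m))

    edits: list[SourceEdit] = []
    for op, li, ri in ops:
        if edits and edits[-1].op == op:
            seg = edits[-1]
            seg.left_lines = (seg.left_lines[0], li + (op != "insert"))
            seg.right_lines = (seg.right_lines[0], ri + (op != "delete"))
            seg.text.append(a[li] if op != "insert" else b[ri])
        else:
            edits.append(
                SourceEdit(
                    op,
                    (li, li + (op != "insert")),
                    (ri, ri + (op != "delete")),
                    [a[li] if op != "insert" else b[ri]],
                )
            )
    return edits


def apply_edits(left: str, edits: list[SourceEdit]) -> str:
    """Reconstruct the right-hand source from the left and an edit script."""
    out: list[str] = []
    for e in edits:
        if e.op in ("equal", "insert"):
            out.extend(e.text)
    return "\n".join(out)


# --------------------------------------------------------------------------
# output deltas

@dataclass
class OutputDelta:
    """Comparison of one positional output pair between two executions."""

    position: int
    change: str  # added | removed | modified | unchanged
    content_kind: str  # text | image | error | other
    detail: dict = field(default_factory=dict)


def _output_kind(out: CellOutput) -> str:
    if out.output_kind == "error":
        return "error"
    if any(m.startswith("image/") for m in out.mime_bundle):
        return "image"
    if "text/plain" in out.mime_bundle:
        return "text"
    return "other"


def _output_text(out: CellOutput) -> str:
    if out.output_kind == "error":
        return f"{out.error_name}: {out.error_value}"
    return out.mime_bundle.get("text/plain", "")


def _image_mime(out: CellOutput) -> str | None:
    for mime in sorted(out.mime_bundle):
        if mime.startswith("image/"):
            return mime
    return None


def _compare_pair(position: int, left: CellOutput, right: CellOutput) -> OutputDelta:
    kind = _output_kind(left)
    if kind == "image":
        lm, rm = _image_mime(left), _image_mime(right)
        lbytes = left.image_bytes(lm) if lm else b""
        rbytes = right.image_bytes(rm) if rm else b""
        same = lm == rm and lbytes == rbytes
        return OutputDelta(
            position,
            "unchanged" if same else "modified",
            "image",
            {"bytes_equal": same, "left_size": len(lbytes), "right_size": len(rbytes)},
        )
    ltext, rtext = _output_text(left), _output_text(right)
    same = ltext == rtext and left == right
    detail = {"edits": line_diff(ltext, rtext)} if kind in ("text", "error") else {}
    return OutputDelta(position, "unchanged" if same else "modified", kind, detail)


def diff_outputs(left: list[CellOutput], right: list[CellOutput]) -> list[OutputDelta]:
    """Pair outputs positionally within each content kind, then compare.

    An output with no partner on the other side becomes ``removed`` (left
    only) or ``added`` (right only); outputs of different kinds at the same
    document position therefore appear as a removed+added pair.
    """
    deltas: list[OutputDelta] = []
    position = 0
    kinds = ("text", "image", "error", "other")
    grouped = {
        side: {k: [o for o in outs if _output_kind(o) == k] for k in kinds}
        for side, outs in (("left", left), ("right", right))
    }
    for kind in kinds:
        ls, rs = grouped["left"][kind], grouped["right"][kind]
        for i in range(max(len(ls), len(rs))):
            if i < len(ls) and i < len(rs):
                deltas.append(_compare_pair(position, ls[i], rs[i]))
            elif i < len(ls):
                deltas.append(OutputDelta(position, "removed", kind, {"text": _output_text(ls[i])}))
            else:
                deltas.append(OutputDelta(position, "added", kind, {"text": _output_text(rs[i])}))
            position += 1
    return deltas


# --------------------------------------------------------------------------
# execution diffs

@dataclass
class DiffResult:
    cell_id: str | None
    left: tuple[str, int]  # (start_time ISO, sequence_index)
    right: tuple[str, int]
    source_edits: list[SourceEdit]
    output_deltas: list[OutputDelta]
    identical: bool


def select_execution_pair(cell: Cell, t_left, t_right, left_index: int | None = None, right_index: int | None = None):
    """Resolve two stored executions of a cell by their start times.

    Start times identify runs; when several runs share a start time the
    sequence index disambiguates (defaulting to 0 when exactly one record
    matches, raising :class:`AmbiguousExecution` otherwise).
    """
    return (
        _resolve(cell, t_left, left_index),
        _resolve(cell, t_right, right_index),
    )


def _resolve(cell: Cell, t, index: int | None) -> ExecutionRecord:
    ts = to_utc_ms(parse_timestamp(t) if isinstance(t, str) else t)
    matches = [r for r in list_executions(cell) if r.start_time == ts]
    if not matches:
        raise NoSuchExecution(f"no execution starting at {format_timestamp(ts)}")
    if index is None:
        if len(matches) > 1:
            raise AmbiguousExecution(
                f"{len(matches)} executions start at {format_timestamp(ts)}; give a sequence index"
            )
        return matches[0]
    for r in matches:
        if r.sequence_index == index:
            return r
    raise NoSuchExecution(f"no execution at {format_timestamp(ts)} with index {index}")


def diff_executions(left: ExecutionRecord, right: ExecutionRecord, cell_id: str | None = None) -> DiffResult:
    """Structured difference between two runs: sources and outputs."""
    source_edits = line_diff(left.source_snapshot, right.source_snapshot)
    output_deltas = diff_outputs(left.outputs_snapshot, right.outputs_snapshot)
    identical = all(e.op == "equal" for e in source_edits) and all(
        d.change == "unchanged" for d in output_deltas
    )
    return DiffResult(
        cell_id=cell_id,
        left=(format_timestamp(left.start_time), left.sequence_index),
        right=(format_timestamp(right.start_time), right.sequence_index),
        source_edits=source_edits,
        output_deltas=output_deltas,
        identical=identical,
    )


# --------------------------------------------------------------------------
# rendering

def render_diff(d: DiffResult, style: str = "plain") -> str:
    """Render a diff as text.

    ``plain`` prefixes deleted lines with ``"- "`` and inserted lines with
    ``"+ "``; ``marked`` wraps deletions in ``[-...-]`` and insertions in
    ``{+...+}`` — the deletion/addition (red/green) roles.  Image changes
    render as a single indicator line with byte sizes.
    """
    if style not in ("plain", "marked"):
        raise ValueError(f"unknown style {style!r}")
    lines: list[str] = [f"--- execution {d.left[0]}#{d.left[1]}", f"+++ execution {d.right[0]}#{d.right[1]}"]
    lines.append("source:")
    lines.extend(_render_edits(d.source_edits, style, indent="  "))
    if d.output_deltas:
        lines.append("outputs:")
        for delta in d.output_deltas:
            lines.extend(_render_delta(delta, style))
    return "\n".join(lines) + "\n"


def _mark(line: str, role: str, style: str) -> str:
    if style == "plain":
        return ("- " if role == "delete" else "+ ") + line
    return f"[-{line}-]" if role == "delete" else f"{{+{line}+}}"


def _render_edits(edits: list[SourceEdit], style: str, indent: str = "") -> list[str]:
    rendered: list[str] = []
    for e in edits:
        if e.op == "equal":
            rendered.extend(indent + "  " + line for line in e.text)
        else:
            role = "delete" if e.op == "delete" else "insert"
            rendered.extend(indent + _mark(line, role, style) for line in e.text)
    return rendered


def _render_delta(delta: OutputDelta, style: str) -> list[str]:
    head = f"  [{delta.position}] {delta.content_kind} {delta.change}"
    if delta.content_kind == "image" and delta.change == "modified":
        return [
            head
            + f": image content changed ({delta.detail['left_size']} bytes -> {delta.detail['right_size']} bytes)"
        ]
    lines = [head]
    if delta.change == "modified" and "edits" in delta.detail:
        lines.extend(_render_edits(delta.detail["edits"], style, indent="    "))
    elif delta.change in ("added", "removed") and delta.detail.get("text"):
        role = "insert" if delta.change == "added" else "delete"
        lines.extend("    " + _mark(line, role, style) for line in delta.detail["text"].split("\n"))
    return lines


def invert(d: DiffResult) -> DiffResult:
    """The reverse diff: deletes and inserts exchanged, sides swapped."""
    edits = [
        SourceEdit(
            {"delete": "insert", "insert": "delete"}.get(e.op, e.op),
            e.right_lines,
            e.left_lines,
            list(e.text),
        )
        for e in d.source_edits
    ]
    deltas = [
        OutputDelta(
            x.position,
            {"added": "removed", "removed": "added"}.get(x.change, x.change),
            x.content_kind,
            dict(x.detail),
        )
        for x in d.output_deltas
    ]
    return DiffResult(d.cell_id, d.right, d.left, edits, deltas, d.identical)
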