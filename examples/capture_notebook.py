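"""Capture per-cell execution provenance in a notebook.

Generates a small synthetic notebook, runs every code cell twice through
the deterministic mock executor under a mock clock, and prints the stored
execution history of each cell: every run keeps its start time and a
human-readable elapsed duration, and the last record is always the most
recent run.
"""

from provlink import FixtureSpec, humanize_duration, list_executions, write_notebook
from provlink.fixtures import generate_notebook

nb = generate_notebook(FixtureSpec(seed=1, n_cells=3, runs_per_cell=2))

for position, cell in enumerate(nb.code_cells(), start=1):
    print(f"cell {position}: {cell.source.splitlines()[0]} ...")
    for record in list_executions(cell):
        print(
            f"  run @ {record.start_time.isoformat()}  took {humanize_duration(record.elapsed_ms)}"
        )

document = write_notebook(nb)
print(f"\nnotebook document: {len(document)} bytes, "
      f"{sum(len(list_executions(c)) for c in nb.code_cells())} execution records")
print("each record snapshots the cell source and outputs at run time;")
print("re-running only ever appends — earlier records never change.")
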