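"""Compare two executions of the same cell, selected by start time.

Simulates a user editing a cell between two runs: the second execution has
one changed source line and a different output.  The diff pairs the two
runs by their start times, computes a minimal line edit script, and renders
it with deletion/insertion markers (the red/green roles of a review tool).
"""

from provlink import FixtureSpec, diff_executions, render_diff, select_execution_pair
from provlink.fixtures import generate_notebook
from provlink.notebook import list_executions

nb = generate_notebook(FixtureSpec(seed=2, n_cells=1, runs_per_cell=2))
cell = nb.code_cells()[0]

first, second = list_executions(cell)
# the user tweaked a constant before the second run
second.source_snapshot = first.source_snapshot.replace("*", "* 2 *")
second.outputs_snapshot = []

left, right = select_execution_pair(cell, first.start_time, second.start_time)
result = diff_executions(left, right, cell_id=cell.stable_id)

print(render_diff(result, style="plain"))
print(f"identical: {result.identical}")
print(f"{sum(e.op != 'equal' for e in result.source_edits)} changed source segments, "
      f"{sum(d.change != 'unchanged' for d in result.output_deltas)} changed outputs")
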