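# provlink

A provenance toolkit for experimental science: it captures, represents,
compares and queries the **complete path** of an experiment — who did what,
with which instruments and settings, on which materials, following which
plans — together with the execution history of the computational notebooks
that analysed the data.

It is written for researchers and data stewards (the motivating setting is
biological imaging: confocal, patch-clamp fluorometry, PALM/dSTORM) who
need to answer questions like *"which laser power produced this figure, and
which notebook run computed it?"* long after the experiment ended.

## The model

Everything maps into one RDF graph over three vocabularies — W3C **PROV-O**
(`prov:Entity`, `prov:Agent`, `prov:Activity`), **P-Plan** (`p-plan:Plan`,
`p-plan:Step`, `p-plan:Variable` and their wiring), and the
**REPRODUCE-ME** extension (`repr:Experiment`, `repr:Notebook`, datasets,
instrument parts, settings, roles, execution time). An experiment
description has eight components: data, agents, activities, plans, steps,
settings, instruments and materials; the experiment itself is a plan, and a
computational notebook attaches to it as a sub-plan
(`notebook p-plan:isSubPlanOfPlan experiment`).

On the notebook side, every run of a code cell is recorded in the cell's
own metadata as an execution record — start and end time, elapsed
milliseconds, and snapshots of the source and outputs — so the document
stays a perfectly valid `.ipynb` that any notebook reader opens. In RDF,
each code cell is a `p-plan:Step` with one input variable (its source) and
one output variable (its latest outputs); each execution is a
`prov:Activity` with `prov:startedAtTime`, `prov:endedAtTime` and
`repr:executionTime`. Two runs of a cell can be selected by start time and
diffed content-wise (minimal line edit script for sources; positional,
byte-exact comparison for image outputs).

Competency questions run as SPARQL over the merged graph, including the two
canonical path queries (the experiment path and the notebook path), and the
ProvTrack view renders the same graph as a typed node-link tree rooted at
the experiment, with path-to-root tracing and node/edge search.

## Worked example

```python
from provlink import FixtureSpec, complete_path_notebook, complete_path_experiment
from provlink.fixtures import generate_linked_store

store, experiment_id, notebook_id = generate_linked_store(
    FixtureSpec(seed=1, n_cells=3, runs_per_cell=2))

print(len(complete_path_notebook(store, notebook_id)))    # 4
print(len(complete_path_experiment(store, experiment_id)))  # 256
```

The notebook path query returns **4** rows: the notebook has 3 code cells
with 2 executions each, but the first cell has no predecessor and the step
order is a mandatory pattern, so only steps 2 and 3 contribute
(2 steps × 2 executions). The experiment path query returns **256** rows —
the cross product of 2 agents × 2 images × 2 instrument settings × 8
plan variables (2 SOP variables + 6 notebook variables) × the step
input/output branches (2 steps × 2 variables) — which is why the toolkit
also ships the split-query ProvTrack view for browsing instead of reading
raw tables. An experiment whose description lacks a component (say, no
instruments) yields **0** rows: incomplete metadata silently empties the
join rather than erroring.

Execution durations humanize the way people read them: `41.3ms`,
`2 min 35s`.

The same flows are scriptable from the shell:

```bash
provlink generate --seed 1 --cells 3 --runs 2 --profile screen \
    --store store.json --out nb.ipynb
provlink query store.json --listing 2 --out rows.csv    # 4 rows
provlink export-rdf nb.ipynb --out nb.ttl               # canonical turtle
provlink import-rdf nb.ttl --out back.ipynb             # the reproducibility service
provlink graph store.json --experiment exp-screen-1 --out view.json
```

`provlink diff NB --cell ID --left T1 --right T2` exits 0 when the two
executions are identical, 1 when they differ, 2 on error.

Each script in `examples/` demonstrates one capability end to end and
prints what the numbers mean.

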