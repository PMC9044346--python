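"""Deterministic synthetic notebooks and microscopy-style experiments.

Everything in the test suite and the examples runs on data generated here:
no download, no kernel, no wall clock.  Notebooks get synthetic code cells,
a table-driven mock executor and a mock clock (epoch 2020-01-01T00:00:00Z,
cell starts one second apart, half-second run durations), so captured
provenance — and every artifact derived from it — is byte-reproducible from
a seed.  Experiments follow profiles shaped after single-molecule and
confocal microscopy studies: confocal patch-clamp fluorometry (``cpcf``),
localization microscopy (``palm_dstorm``), and an imaging screen
(``screen``) that exercises every component of the experiment model —
agents with roles, a dataset of images, an instrument with parts and
settings linked to the images it produced, materials, a standard operating
procedure sub-plan, and ordered steps with named input/output variables,
availability URLs and literature references.
"""

from __future__ import annotations

import hashlib
import io
import random
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone

from PIL import Image

from .experiment import (
    AgentRef,
    DatasetRef,
    ExperimentStore,
    ImageRef,
    InstrumentPart,
    InstrumentRecord,
    MaterialRecord,
    PlanRecord,
    SettingEntry,
    StepRecord,
    VariableRecord,
)
from .notebook import (
    Cell,
    MockClock,
    MockExecutor,
    Notebook,
    error_output,
    execute_and_capture,
    image_output,
    text_output,
)
from .rdf import DEFAULT_BASE

EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)

PROFILES: dict[str, dict[str, int]] = {
    "minimal": dict(agents=0, datasets=0, images=0, instruments=0, parts=0, settings=0, materials=0, steps=0, subplans=0),
    "cpcf": dict(agents=2, datasets=1, images=2, instruments=2, parts=2, settings=2, materials=2, steps=3, subplans=1),
    "palm_dstorm": dict(agents=1, datasets=2, images=3, instruments=1, parts=1, settings=3, materials=1, steps=2, subplans=1),
    "screen": dict(agents=2, datasets=1, images=2, instruments=1, parts=1, settings=2, materials=2, steps=2, subplans=1),
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data generators.

    ``output_mix`` gives the proportion of text, image and error outputs
    among generated code cells; proportions must sum to one.
    """

    seed: int = 1
    n_cells: int = 3
    runs_per_cell: int = 2
    output_mix: dict[str, float] = field(default_factory=lambda: {"text": 0.6, "image": 0.2, "error": 0.2})
    experiment_profile: str = "screen"

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.runs_per_cell < 0:
            raise ValueError("counts must be non-negative")
        if abs(sum(self.output_mix.values()) - 1.0) > 1e-9:
            raise ValueError("output_mix proportions must sum to 1")
        if self.experiment_profile not in PROFILES:
            raise ValueError(f"unknown profile {self.experiment_profile!r}; choose from {sorted(PROFILES)}")


def _rng_uuid(rng: random.Random) -> str:
    return str(uuid.UUID(int=rng.getrandbits(128), version=4))


def tiny_png(rng: random.Random, size: int = 8) -> bytes:
    """A deterministic small RGB PNG derived from the generator state."""
    img = Image.new("RGB", (size, size))
    img.putdata([(rng.randrange(256), rng.randrange(256), rng.randrange(256)) for _ in range(size * size)])
    buffer = io.BytesIO()
    img.save(buffer, format="PNG", optimize=False)
    return buffer.getvalue()


def _pick_kind(rng: random.Random, mix: dict[str, float]) -> str:
    kinds = sorted(mix)
    return rng.choices(kinds, weights=[mix[k] for k in kinds], k=1)[0]


def generate_notebook(spec: FixtureSpec) -> Notebook:
    """A seeded notebook: code cells with captured execution provenance.

    ``n_cells`` code cells (plus one markdown header when any exist), each
    executed ``runs_per_cell`` times through the mock executor under the
    mock clock.  The same seed always yields a byte-identical document.
    """
    nb, executor, clock = generate_unexecuted_notebook(spec)
    for _ in range(spec.runs_per_cell):
        execute_and_capture(nb, executor, clock)
    return nb


def generate_unexecuted_notebook(spec: FixtureSpec) -> tuple[Notebook, MockExecutor, MockClock]:
    """The notebook before any run, with its executor and clock.

    Useful when a test wants to drive the capture loop itself.
    """
    rng = random.Random(spec.seed)
    cells: list[Cell] = []
    table = {}
    if spec.n_cells > 0:
        cells.append(
            Cell(cell_type="markdown", source="# Synthetic analysis notebook\nGenerated fixture.", stable_id=_rng_uuid(rng))
        )
    for i in range(spec.n_cells):
        a, b = rng.randrange(1, 100), rng.randrange(1, 100)
        source = f"x{i} = {a}\ny{i} = x{i} * {b}\nprint(y{i})"
        kind = _pick_kind(rng, spec.output_mix)
        if kind == "text":
            outputs = [text_output(str(a * b)), ]
        elif kind == "image":
            outputs = [image_output(tiny_png(rng))]
        else:
            outputs = [error_output("ValueError", f"synthetic failure in cell {i}")]
        table[source] = outputs
        cells.append(Cell(cell_type="code", source=source, stable_id=_rng_uuid(rng)))
    nb = Notebook(
        notebook_metadata={"kernelspec": {"display_name": "Python 3", "language": "python", "name": "python3"}},
        cells=cells,
        stable_id=_rng_uuid(rng),
    )
    executor = MockExecutor(table)
    clock = MockClock(EPOCH, tick_ms=500)
    return nb, executor, clock


class HashingMockExecutor(MockExecutor):
    """Mock executor for arbitrary sources: output derived from a hash.

    Pure and seed-parameterized, so two runs in the "same environment"
    (same seed) agree and runs under different seeds differ — the shape of
    reproducing a notebook in different environments.
    """

    def __init__(self, seed: int = 0):
        super().__init__()
        self.seed = seed
        self.environment.packages = {"provlink-mock": str(seed)}

    def execute(self, source: str):
        digest = hashlib.sha1(f"{self.seed}:{source}".encode()).hexdigest()[:10]
        return [text_output(f"mock:{digest}")]


# --------------------------------------------------------------------------
# experiments

_AGENTS = [("a-odonnell", "M. O'Donnell", "principal investigator"), ("a-weber", "K. Weber", "doctoral researcher"), ("a-fischer", "T. Fischer", "microscopy operator")]
_INSTRUMENTS = ["LSM 880 confocal microscope", "Patch-clamp amplifier EPC 10", "N-STORM super-resolution system"]
_PARTS = ["objective 63x/1.4 oil", "argon laser line", "EMCCD camera"]
_SETTINGS = [("excitation wavelength", 488, "nm"), ("laser power", 2.5, "mW"), ("exposure time", 50, "ms"), ("pinhole diameter", 1.0, "AU")]
_MATERIALS = [("chemical", "cAMP solution"), ("protein", "HCN2 channel protein"), ("plasmid", "pEGFP-N1"), ("chemical", "Alexa Fluor 647 dye")]
_TITLES = {
    "cpcf": "Confocal patch-clamp fluorometry of HCN2 channel activation",
    "palm_dstorm": "PALM/dSTORM localization imaging of membrane receptors",
    "screen": "Focused mitotic chromosome condensation screen using HeLa cells",
    "minimal": "",
}


def generate_experiment(spec: FixtureSpec):
    """A seeded eight-component experiment record for the chosen profile.

    The ``screen`` profile exercises every field: agent roles, dataset
    images, instrument parts with settings and image links, materials, an
    SOP sub-plan with its own step and variables, and experiment-level
    steps whose outputs carry availability URLs and references.
    """
    store, experiment_id = generate_store(spec)
    return store.experiments[experiment_id]


def generate_store(spec: FixtureSpec, base: str = DEFAULT_BASE) -> tuple[ExperimentStore, str]:
    """An experiment store built through the mutation API, version history included."""
    rng = random.Random(spec.seed + 1)
    counts = PROFILES[spec.experiment_profile]
    clock = MockClock(EPOCH, tick_ms=1000)
    store = ExperimentStore(base=base, clock=clock.now)
    experiment_id = f"exp-{spec.experiment_profile}-{spec.seed}"
    author = _AGENTS[0][0] if counts["agents"] else None

    agents = [AgentRef(*(_AGENTS[i % len(_AGENTS)])) for i in range(counts["agents"])]
    store.create_experiment(experiment_id, _TITLES[spec.experiment_profile], EPOCH, agents=agents, author=author)

    image_ids: list[str] = []
    for d in range(counts["datasets"]):
        images = []
        for i in range(counts["images"]):
            image_id = f"img-{d}-{i}"
            image_ids.append(image_id)
            images.append(ImageRef(id=image_id, name=f"tile {d}-{i} ({rng.randrange(1, 512)} nm px)"))
        store.add_dataset(experiment_id, DatasetRef(id=f"ds-{d}", name=f"acquisition set {d + 1}", images=images), author=author)

    for j in range(counts["instruments"]):
        parts = []
        for p in range(counts["parts"]):
            settings = [SettingEntry(*_SETTINGS[(p + s) % len(_SETTINGS)]) for s in range(counts["settings"])]
            parts.append(InstrumentPart(id=f"part-{j}-{p}", name=_PARTS[p % len(_PARTS)], settings=settings))
        instrument = InstrumentRecord(
            id=f"inst-{j}",
            name=_INSTRUMENTS[j % len(_INSTRUMENTS)],
            parts=parts,
            linked_images=list(image_ids),
        )
        store.add_instrument(experiment_id, instrument, author=author)

    for m in range(counts["materials"]):
        kind, name = _MATERIALS[m % len(_MATERIALS)]
        store.add_material(experiment_id, MaterialRecord(id=f"mat-{m}", kind=kind, name=name, attributes={"lot": str(rng.randrange(10_000))}), author=author)

    subplan_ids = []
    for p in range(counts["subplans"]):
        plan_id = f"sop-{p}"
        subplan_ids.append(plan_id)
        store.add_subplan(
            experiment_id,
            PlanRecord(id=plan_id, kind="sop", name=f"sample preparation SOP v{p + 1}", body="fix cells; stain; mount; image"),
            author=author,
        )

    previous = None
    for s in range(counts["steps"]):
        step_id = f"step-{s}"
        step = StepRecord(
            id=step_id,
            plan_id=experiment_id,
            name=f"acquisition step {s + 1}",
            predecessor=previous,
            inputs=[VariableRecord(id=f"var-{step_id}-in", name=f"sample state {s}")],
            outputs=[
                VariableRecord(
                    id=f"var-{step_id}-out",
                    name=f"image stack {s}",
                    availability_url=f"https://data.example.org/{experiment_id}/{step_id}",
                    reference=f"doi:10.5281/zenodo.{1000 + s}",
                )
            ],
        )
        store.add_step(experiment_id, step, author=author)
        previous = step_id
    # the SOP contributes its own step so sub-plan variables exist
    for plan_id in subplan_ids:
        store.add_step(
            experiment_id,
            StepRecord(
                id=f"step-{plan_id}",
                plan_id=plan_id,
                name="prepare sample",
                inputs=[VariableRecord(id=f"var-{plan_id}-in", name="HeLa cell culture")],
                outputs=[VariableRecord(id=f"var-{plan_id}-out", name="mounted specimen")],
            ),
            author=author,
        )
    return store, experiment_id


def generate_linked_store(spec: FixtureSpec, base: str = DEFAULT_BASE) -> tuple[ExperimentStore, str, str]:
    """Store with the profile experiment plus a generated notebook linked to it."""
    store, experiment_id = generate_store(spec, base=base)
    nb = generate_notebook(spec)
    notebook_id = store.link_notebook(experiment_id, nb)
    return store, experiment_id, notebook_id
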