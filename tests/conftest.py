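import pytest

from provlink import FixtureSpec, generate_linked_store, generate_notebook


@pytest.fixture
def spec():
    return FixtureSpec(seed=1, n_cells=3, runs_per_cell=2)


@pytest.fixture
def nb(spec):
    return generate_notebook(spec)


@pytest.fixture
def linked_store(spec):
    return generate_linked_store(spec)
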