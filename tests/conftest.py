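import pytest

from mitosrna import (
    SimulationSpec,
    build_index,
    collapse,
    make_toy_references,
    select_mt_associated,
    simulate_library,
)


@pytest.fixture(scope="session")
def toy_refs():
    return make_toy_references(seed=1)


@pytest.fixture(scope="session")
def mt_index(toy_refs):
    return build_index([(toy_refs.genome.id, toy_refs.genome.sequence, True)])


@pytest.fixture(scope="session")
def sim_mt_library(toy_refs, mt_index):
    """A mitochondria-only simulated library with its truth table and
    mitochondrial placements (shared across read-only tests)."""
    spec = SimulationSpec(seed=7, n_reads=20_000, mt_fraction=1.0)
    reads, truth = simulate_library(spec, toy_refs)
    lib = collapse(reads, "sim")
    mt_lib, placements = select_mt_associated(lib, mt_index)
    return {
        "spec": spec,
        "reads": reads,
        "truth": truth,
        "library": lib,
        "mt_library": mt_lib,
        "placements": placements,
    }
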