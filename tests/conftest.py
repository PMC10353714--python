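import pytest

from leukosv import cohort_sim, io_formats, pipeline
from leukosv.sv_merge import MatchParams
from leukosv.types import PipelineConfig


@pytest.fixture(scope="session")
def contigs():
    return io_formats.load_contigs()


@pytest.fixture(scope="session")
def cytobands():
    return io_formats.CytobandMap.from_file()


@pytest.fixture(scope="session")
def genes():
    return io_formats.read_gene_models()


@pytest.fixture(scope="session")
def genes_by_symbol(genes):
    return {g.symbol: g for g in genes}


@pytest.fixture(scope="session")
def blacklist(cytobands):
    return io_formats.build_blacklist(io_formats.read_blacklist(), cytobands)


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def match_params():
    return MatchParams()


@pytest.fixture(scope="session")
def small_cohort():
    """6+6 cohort used by tests that only need structure, not statistics."""
    return cohort_sim.simulate_cohort(cohort_sim.SimConfig(n_per_subtype=6,
                                                           seed=7))


@pytest.fixture(scope="session")
def full_cohort():
    """The study-scale 30+30 cohort (seed 1) used for parameter recovery."""
    return cohort_sim.simulate_cohort(cohort_sim.SimConfig(n_per_subtype=30,
                                                           seed=1))


@pytest.fixture(scope="session")
def full_results(full_cohort):
    return pipeline.process_cohort(full_cohort.calls, full_cohort.samples)
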