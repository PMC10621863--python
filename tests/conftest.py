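import pytest
from hypothesis import settings

from hdrmave import counts_io, simulate

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    """A 40-codon library small enough for fast end-to-end exercises."""
    return simulate.SimConfig(
        codon_range=(1280, 1319),
        n_missense_per_codon=2,
        n_synonymous=10,
        n_nonsense=10,
        barcodes_per_variant=2.0,
        n_cells_integrated=80_000,
        sequencing_depth=200_000,
        n_replicates=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate.generate_library(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_library):
    bmap, truth = small_library
    return simulate.simulate_sort_counts(bmap, truth, small_config)


@pytest.fixture(scope="session")
def small_vcounts(small_library, small_sim):
    bmap, _ = small_library
    vcounts, _ = counts_io.collapse_to_variants(small_sim.counts, bmap)
    return vcounts
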