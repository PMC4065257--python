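import pytest

from indelmark import (
    SimConfig,
    build_haplotype,
    plant_demo_loci,
    simulate,
)


@pytest.fixture(scope="session")
def demo():
    """The six planted demonstration loci (fixed internal seed)."""
    return plant_demo_loci()


@pytest.fixture(scope="session")
def demo_haplotypes(demo):
    return {name: build_haplotype(demo.genome, t) for name, t in demo.tracks.items()}


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded genome + tracks draw shared across tests."""
    return simulate(SimConfig(rng_seed=7, n_chroms=2, chrom_length=60_000))
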