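import pytest

from metaprof import simulate as sim
from metaprof.markerdb import build_marker_database


@pytest.fixture(scope="session")
def small_universe():
    """Four species, three genomes each, one cross-species shared family."""
    genomes_by_species, taxonomy = sim.simulate_universe(
        n_species=4,
        genomes_per_species=3,
        n_core=20,
        n_accessory=5,
        seed=101,
        shared_family_pairs=1,
    )
    return genomes_by_species, taxonomy


@pytest.fixture(scope="session")
def small_db(small_universe):
    genomes_by_species, taxonomy = small_universe
    return build_marker_database(genomes_by_species, taxonomy)
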