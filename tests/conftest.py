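import pytest

import repinscan as rs
from repinscan.simulate import GI_SEED, GII_SEED, GIII_SEED


@pytest.fixture(scope="session")
def small_sim():
    """A 150 kb genome with 20 GI + 10 GII REPINs and 8 decayed singlets."""
    cfg = rs.SimulationConfig(
        genome_length=150_000,
        gene_density=0.6,
        families=[
            rs.RepinFamilySpec("GI", GI_SEED, 71, 20),
            rs.RepinFamilySpec("GII", GII_SEED, 110, 10),
        ],
        n_singlets=8,
    )
    genome, truth = rs.simulate_genome(cfg, seed=11)
    return genome, truth


@pytest.fixture(scope="session")
def small_occurrences(small_sim):
    """Matched occurrences (d=1 around discovered seeds) on the 150 kb genome."""
    genome, truth = small_sim
    space = rs.extragenic_space(genome)
    pool = rs.family_pool([GI_SEED, GII_SEED], 1, labels=["GI", "GII"])
    occ = [o for o in rs.match_in_space(pool, genome, space) if o.extragenic]
    return genome, truth, occ
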