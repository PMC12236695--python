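import numpy as np
import pytest

from mitoscan import GeneMapConfig, SimConfig
from mitoscan.ancestry_io import AimSite, PosteriorMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_sim_config():
    """A seconds-fast simulation: 2 chromosomes, 60 individuals."""
    return SimConfig(
        n_individuals=60,
        n_generations=8,
        admixture_prop=0.5,
        mito_init_freq=0.5,
        chromosomes=(("chr1", 1.0), ("chr2", 1.0)),
        n_aims_per_chrom=40,
        gene_map=GeneMapConfig(4, 8, 28),
        seed=11,
    )


def make_matrix(values, individuals=None, mito_row=True):
    """PosteriorMatrix from a 2-D array; last row is the mito AIM when
    mito_row is set."""
    values = np.asarray(values, dtype=float)
    n_sites, n_ind = values.shape
    individuals = individuals or [f"i{j}" for j in range(n_ind)]
    sites = [
        AimSite("chr1", 100 * (i + 1), "nuclear")
        for i in range(n_sites - (1 if mito_row else 0))
    ]
    if mito_row:
        sites.append(AimSite("chrM", 1, "mito"))
    return PosteriorMatrix(values, individuals, sites)


@pytest.fixture
def matrix_factory():
    return make_matrix
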