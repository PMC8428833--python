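import numpy as np
import pytest

import panpav


@pytest.fixture(scope="session")
def small_sim():
    """A 30-accession, 200-gene noise-free simulated pan-genome."""
    cfg = panpav.SimConfig(n_accessions=30, n_genes=200, seed=11)
    return panpav.simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    return small_sim.truth_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pav_matrix(rng, n_genes, n_accessions):
    pres = rng.integers(0, 2, size=(n_genes, n_accessions), dtype=np.uint8)
    # a pan-genome matrix has no all-absent gene
    for gi in np.flatnonzero(pres.sum(axis=1) == 0):
        pres[gi, rng.integers(n_accessions)] = 1
    return panpav.PavMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"a{j}" for j in range(n_accessions)],
        pres,
    )
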