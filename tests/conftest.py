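import numpy as np
import pytest

from peripatry.variant_io import MISSING, VariantTable


def make_table(genotypes, depths=None, loci=None, pops=("A", "A", "B", "B")):
    """Small VariantTable helper: genotypes is a (sites, individuals) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    s, n = g.shape
    if depths is None:
        depths = np.full((s, n), 10, dtype=np.int32)
    individuals = [f"ind{i}" for i in range(n)]
    return VariantTable(
        g,
        np.asarray(depths, dtype=np.int32),
        loci or [f"loc{i}" for i in range(s)],
        np.arange(1, s + 1),
        individuals,
        {ind: pops[i] for i, ind in enumerate(individuals)},
    )


@pytest.fixture
def four_ind_table():
    """3 sites x 4 individuals (2 per population), no missing data."""
    return make_table(
        [
            [0, 1, 0, 0],
            [1, 2, 0, 1],
            [0, 0, 0, 0],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_table(rng, n_sites=20, n_ind=6, n_loci=5, miss_p=0.2):
    g = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
    miss = rng.random((n_sites, n_ind)) < miss_p
    g[miss] = MISSING
    depths = rng.poisson(8, size=(n_sites, n_ind)).astype(np.int32)
    loci = [f"loc{rng.integers(n_loci)}" for _ in range(n_sites)]
    pops = tuple("A" if i < n_ind // 2 else "B" for i in range(n_ind))
    return make_table(g, depths, loci, pops)
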