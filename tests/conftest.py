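import dendropy
import numpy as np
import pandas as pd
import pytest

import divspace as dv


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_species_tree():
    """A seeded ~30-species tree shared by tests that just need a valid tree."""
    genus = dv.gen_genus_phylogeny(10, seed=11)
    sp2g = {f"g{i:02d}_s{j}": f"g{i:02d}" for i in range(1, 11) for j in range(1, 4)}
    return dv.expand_genus_tree(genus, sp2g, seed=12), sp2g


def random_community(rng: np.random.Generator, n_species: int) -> np.ndarray:
    """Random relative-abundance vector (all entries positive)."""
    p = rng.dirichlet(np.ones(n_species))
    return p / p.sum()


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid similarity matrix: symmetric, unit diagonal, [0, 1]."""
    z = rng.uniform(0, 1, size=(n, n))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 1.0)
    return z
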