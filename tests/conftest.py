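import numpy as np
import pandas as pd
import pytest

from floralint import PhyloTree, TraitTable
from floralint.data_io import DEFAULT_TRAITS


@pytest.fixture
def hand_tree():
    """Three-tip tree with hand-checkable shared path lengths."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def exact_correlation_data(R, n, rng):
    """N x T data whose sample correlation matrix is exactly R.

    Columns of an orthonormalized centred Gaussian draw have exactly zero
    pairwise sample correlation; multiplying by a Cholesky factor of R
    plants R exactly (correlation is scale-free).
    """
    R = np.asarray(R, float)
    t = R.shape[0]
    z = rng.standard_normal((n, t))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    return q @ np.linalg.cholesky(R).T


def make_trait_table(species_means, n_per_species, rng, cv=0.05):
    """Small valid TraitTable around given per-species mean vectors."""
    rows = []
    for sp, means in species_means.items():
        means = np.asarray(means, float)
        for i in range(n_per_species):
            draw = np.abs(means * (1 + cv * rng.standard_normal(len(means)))) + 1e-6
            rows.append(
                {"species_id": sp, "individual_id": f"{sp}_{i}", **dict(zip(DEFAULT_TRAITS, draw))}
            )
    return TraitTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def lonicera_bundle():
    """One shared synthetic study-scale dataset."""
    from floralint import make_dataset

    return make_dataset("lonicera-like", seed=11)
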