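import numpy as np
import pytest

from commstab.stability import CommunityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_community(rng, n_species=None, n_years=None, site_id="s"):
    """Random strictly positive community matrix (lognormal abundances)."""
    n_species = n_species or int(rng.integers(3, 31))
    n_years = n_years or int(rng.integers(4, 18))
    abundance = np.exp(rng.normal(1.0, 1.0, size=(n_species, n_years)))
    return CommunityMatrix(
        site_id=site_id,
        species=[f"sp{i}" for i in range(n_species)],
        years=list(range(2000, 2000 + n_years)),
        abundance=abundance,
    )


@pytest.fixture
def two_species_matrix():
    return CommunityMatrix(
        site_id="s1",
        species=["A", "B"],
        years=[1, 2, 3],
        abundance=np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]]),
    )
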