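import numpy as np
import pandas as pd
import pytest

from tsblup.core import Dataset, GenotypeMatrix, MarkerMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genotypes():
    """2 x 2 opposite-homozygote toy."""
    return GenotypeMatrix(
        individual_ids=["ind1", "ind2"],
        marker_ids=["m1", "m2"],
        dosages=[[0, 2], [2, 0]],
    )


@pytest.fixture
def small_genotypes():
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(6, 10)).astype(float)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(6)],
        marker_ids=[f"m{k}" for k in range(10)],
        dosages=dosages,
    )


@pytest.fixture
def chr1_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{k}" for k in range(5)],
                "chromosome": "1",
                "position": [10, 20, 30, 40, 50],
            }
        )
    )


def random_genotypes(rng, n, m, maf=(0.1, 0.9), prefix=""):
    freqs = rng.uniform(*maf, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    return GenotypeMatrix(
        individual_ids=[f"{prefix}i{k}" for k in range(n)],
        marker_ids=[f"{prefix}m{k}" for k in range(m)],
        dosages=dosages,
    )


def genotypes_to_dataset(genotypes, phenotypes=None, reference_values=None):
    mmap = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": genotypes.marker_ids,
                "chromosome": "1",
                "position": (np.arange(genotypes.n_markers) + 1) * 100,
            }
        )
    )
    if phenotypes is None:
        phenotypes = pd.Series(
            np.zeros(genotypes.n_individuals), index=genotypes.individual_ids
        )
    return Dataset(
        genotypes=genotypes,
        marker_map=mmap,
        phenotypes=phenotypes,
        reference_values=reference_values,
    )
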