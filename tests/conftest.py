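import numpy as np
import pytest

from gamut.kernels import GenotypeMatrix, PhenotypeMatrix, WeightVector
from gamut.simulate import default_bdi_model, stat3_like_pool


@pytest.fixture(scope="session")
def stat3_pool():
    return stat3_like_pool()


@pytest.fixture(scope="session")
def bdi_model():
    return default_bdi_model()


def make_null_dataset(seed: int, n: int = 200, q: int = 5, v: int = 8):
    """Small independent phenotype/genotype pair with LD-structured dosages."""
    rng = np.random.default_rng(seed)
    Y = PhenotypeMatrix(rng.integers(0, 4, (n, q)))
    haps = (rng.random((400, v)) < rng.uniform(0.1, 0.5, v)).astype(float)
    G = GenotypeMatrix(haps[rng.integers(0, 400, n)] + haps[rng.integers(0, 400, n)])
    w = WeightVector.from_maf(G.maf)
    return Y, G, w


@pytest.fixture()
def small_dataset():
    return make_null_dataset(seed=7)
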