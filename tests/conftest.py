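import numpy as np
import pytest

from fslr.regression import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_dataset(rng):
    """50 individuals x 6 SNPs with a weak planted signal on SNP 0."""
    g = (rng.random((50, 6)) < 0.35).astype(np.int8)
    p = np.where(rng.random(50) < 0.8, g[:, 0], 1 - g[:, 0]).astype(np.int8)
    return Dataset(genotypes=g, phenotypes=p)


@pytest.fixture
def null_dataset(rng):
    """2000 x 4, phenotype independent of every SNP."""
    g = (rng.random((2000, 4)) < 0.4).astype(np.int8)
    p = (rng.random(2000) < 0.5).astype(np.int8)
    return Dataset(genotypes=g, phenotypes=p)
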