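import numpy as np
import pandas as pd
import pytest

from ylineage import GenealogyModel, MutationRateSpec, simulate_genealogy
from ylineage.containers import STRHaplotypeTable, VariantMatrix


@pytest.fixture
def rates():
    return MutationRateSpec()


@pytest.fixture
def star_tree():
    return simulate_genealogy(GenealogyModel(n_samples=4, tmrca=1000,
                                             topology="star", seed=11))


def make_str_table(matrix, populations=None, loci=None, longitudes=None):
    matrix = np.asarray(matrix, dtype=np.int64)
    n, k = matrix.shape
    loci = loci or [f"L{j + 1}" for j in range(k)]
    df = pd.DataFrame({"sample": [f"s{i + 1}" for i in range(n)],
                       "population": populations or ["pop1"] * n})
    if longitudes is not None:
        df["longitude"] = longitudes
    for j, locus in enumerate(loci):
        df[locus] = matrix[:, j]
    return STRHaplotypeTable(df)


def make_variant_matrix(genotypes, depth=None, positions=None, ids=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 10
    return VariantMatrix(positions=positions,
                         samples=[f"s{i + 1}" for i in range(n)],
                         genotypes=genotypes,
                         depth=depth, ids=ids)
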