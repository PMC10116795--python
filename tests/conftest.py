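import io

import numpy as np
import pytest
import skbio

from krv.datatypes import CountTable, CovariateDesign, GenotypeMatrix
import pandas as pd


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_tree():
    # ((A:1,B:1):1,C:2):0  -- branches: A=1, B=1, AB=1, C=2
    return skbio.TreeNode.read(io.StringIO("((A:1,B:1)AB:1,C:2)root;"))


@pytest.fixture()
def small_table():
    # s1 has only A, s2 has only C, s3 has A and B equally
    return CountTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C"],
        np.array([[4, 0, 0],
                  [0, 0, 4],
                  [2, 2, 0]]),
    )


@pytest.fixture()
def random_table(rng):
    counts = rng.integers(0, 50, size=(12, 8))
    counts[:, 0] += 1  # avoid all-zero rows
    return CountTable([f"s{i}" for i in range(12)],
                      [f"t{j}" for j in range(8)], counts)


@pytest.fixture()
def genotypes(rng):
    n, m = 20, 6
    dos = rng.integers(0, 3, size=(n, m)).astype(float)
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": np.sort(rng.integers(1, 100_000, m)),
        "id": [f"v{i}" for i in range(m)],
    })
    return GenotypeMatrix([f"s{i}" for i in range(n)], dos, variants)


@pytest.fixture()
def intercept_design():
    def make(sample_ids):
        return CovariateDesign.intercept_only(sample_ids)
    return make
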