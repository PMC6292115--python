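import numpy as np
import pandas as pd
import pytest

from mutpath import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    make_worked_example,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def small_expression(rng):
    """12 genes x 8 samples of log-scale-ish expression."""
    data = rng.normal(8.0, 2.0, size=(12, 8))
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{j}" for j in range(8)]
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))


@pytest.fixture()
def small_collection():
    return GeneSetCollection(
        [
            GeneSet("SET1", "d", frozenset({"g0", "g1", "g2", "g3", "g4"})),
            GeneSet("SET2", "d", frozenset({"g5", "g6", "g7", "g8", "g9", "g10"})),
        ]
    )
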