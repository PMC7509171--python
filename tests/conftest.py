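import numpy as np
import pytest

from tscpath import ExpressionMatrix, GeneSetCollection, ResponseTable


def make_expression(values, gene_prefix="G", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    genes = tuple(f"{gene_prefix}{i + 1}" for i in range(values.shape[0]))
    samples = tuple(f"{sample_prefix}{j + 1}" for j in range(values.shape[1]))
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_expr(rng):
    return make_expression(rng.standard_normal((6, 4)))


@pytest.fixture
def small_sets():
    return GeneSetCollection(
        {"SET_A": ("G1", "G2", "G3"), "SET_B": ("G4", "G5", "G6", "G1")}
    )


def balanced_labels(sample_ids, arm="combination", er="ER+"):
    n = len(sample_ids)
    response = np.array([i % 2 for i in range(n)])
    return ResponseTable(
        tuple(sample_ids), response, tuple([arm] * n), tuple([er] * n)
    )
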