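import numpy as np
import pytest

from dynagsea import ExpressionMatrix, GeneSet, GeneSetCollection, scale_rows


def make_matrix(values, gene_ids=None, time_labels=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = gene_ids or tuple(f"g{i}" for i in range(n))
    time_labels = time_labels or tuple(f"t{j}" for j in range(m))
    return ExpressionMatrix(tuple(gene_ids), tuple(time_labels), values)


def random_scaled(rng, n, m):
    """A random matrix passed through the package's own row scaling."""
    return scale_rows(make_matrix(rng.normal(size=(n, m))))


def collection(*name_members) -> GeneSetCollection:
    return GeneSetCollection(
        tuple(
            GeneSet(name, "test", tuple(members))
            for name, members in name_members
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """4 genes x 5 time points, no missing values, no constant rows."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(size=(4, 5)))
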