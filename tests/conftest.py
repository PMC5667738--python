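import numpy as np
import pytest

from swarmselect import ExpressionMatrix


def two_class_matrix(class0_rows, class1_rows, gene_ids=None):
    """Build a labelled matrix from per-class observation rows."""
    x0 = np.atleast_2d(np.asarray(class0_rows, dtype=float))
    x1 = np.atleast_2d(np.asarray(class1_rows, dtype=float))
    values = np.vstack([x0, x1])
    n_genes = values.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]
    obs_ids = [f"c{i}" for i in range(len(x0))] + [f"a{i}" for i in range(len(x1))]
    labels = ["control"] * len(x0) + ["case"] * len(x1)
    return ExpressionMatrix(values, np.asarray(gene_ids, dtype=object),
                            np.asarray(obs_ids, dtype=object),
                            np.asarray(labels, dtype=object))


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(42)
    return two_class_matrix(rng.lognormal(4, 0.3, (8, 12)), rng.lognormal(4, 0.3, (8, 12)))
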