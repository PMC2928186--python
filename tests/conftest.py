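import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from exprdiv import ExpressionMatrix, OrthologPairSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_expression(values, species="species1", genes=None, tissues=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    genes = genes or [f"g{i:03d}" for i in range(n)]
    tissues = tissues or [f"tissue{j:02d}" for j in range(t)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues), species=species)


@pytest.fixture
def five_gene_pair():
    """Two small aligned matrices with an identity ortholog map."""
    rng = np.random.default_rng(42)
    a = make_expression(rng.uniform(1, 100, size=(5, 8)), species="species1")
    b = make_expression(rng.uniform(1, 100, size=(5, 8)), species="species2")
    pairs = OrthologPairSet(a.gene_ids, b.gene_ids)
    return a, b, pairs
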