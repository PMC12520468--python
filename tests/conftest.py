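import numpy as np
import pandas as pd
import pytest

from dnbtip.io import ExpressionSeries


def make_series(values, timepoints, n_replicates, gene_ids=None):
    """Build an ExpressionSeries from a genes x (T*R) array."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_map = {}
    cols = []
    for tp in timepoints:
        for r in range(1, n_replicates + 1):
            s = f"{tp}_r{r}"
            sample_map[s] = (tp, r)
            cols.append(s)
    data = pd.DataFrame(values, index=gene_ids, columns=cols)
    return ExpressionSeries(data=data, sample_map=sample_map, timepoints=list(timepoints))


@pytest.fixture
def two_group_series():
    """3 genes x 2 timepoints x 3 replicates with simple arithmetic values."""
    vals = np.array(
        [
            [1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [1.0, 1.2, 0.8, 3.2, 3.0, 3.4],
        ]
    )
    return make_series(vals, ["W2", "W3"], 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
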