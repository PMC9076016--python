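import numpy as np
import pandas as pd
import pytest

from gestclock.dataset import ExpressionDataset, stage_from_weeks


def make_dataset(X, gene_names=None, ga_days=None, cell_types=None, subjects=None, layer="counts"):
    """Assemble a small ExpressionDataset from raw pieces."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if gene_names is None:
        gene_names = [f"G{j}" for j in range(m)]
    if ga_days is None:
        ga_days = np.full(n, 100, dtype=int)
    ga_days = np.asarray(ga_days, dtype=int)
    weeks = ga_days // 7
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "subject_id": subjects if subjects is not None else [f"s{i}" for i in range(n)],
            "cell_type": cell_types if cell_types is not None else ["T"] * n,
            "ga_days": ga_days,
            "ga_weeks": weeks,
            "stage": [stage_from_weeks(int(w)) for w in weeks],
        }
    )
    return ExpressionDataset(X, pd.Index(gene_names), meta, layer)


@pytest.fixture
def tiny_counts():
    """3 cells x 4 genes with known integer entries."""
    X = np.array([[1, 0, 2, 0], [0, 3, 0, 0], [5, 1, 1, 2]], dtype=float)
    return make_dataset(X, gene_names=["MT-A", "G1", "G2", "G3"])
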