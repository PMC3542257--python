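import numpy as np
import pandas as pd
import pytest

from tiledep.model import ArrayInfo, ExpressionMatrix

TWO_VS_TWO = [
    ArrayInfo("dep_1", "depleted", 1),
    ArrayInfo("dep_2", "depleted", 2),
    ArrayInfo("ind_1", "induced", 1),
    ArrayInfo("ind_2", "induced", 2),
]


def make_matrix(columns: dict, genes=None) -> ExpressionMatrix:
    """Build a 2v2 ExpressionMatrix from per-array value lists."""
    arrays = [a for a in TWO_VS_TWO if a.array_id in columns]
    n = len(next(iter(columns.values())))
    genes = genes or [f"g{i:03d}" for i in range(n)]
    data = pd.DataFrame(
        {a.array_id: np.asarray(columns[a.array_id], dtype=float) for a in arrays},
        index=pd.Index(genes, name="id"),
    )
    return ExpressionMatrix(data=data, arrays=arrays)


@pytest.fixture
def design_2v2():
    return list(TWO_VS_TWO)


def null_matrix(rng: np.random.Generator, n_genes: int = 2000) -> ExpressionMatrix:
    """Pure-null 2v2 gene-level matrix: per-gene baseline + replicate noise."""
    base = rng.normal(10.0, 1.5, n_genes)
    data = {
        a.array_id: base + rng.normal(0.0, 0.1, n_genes) for a in TWO_VS_TWO
    }
    return make_matrix(data, genes=[f"g{i:05d}" for i in range(n_genes)])
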