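import numpy as np
import pandas as pd
import pytest

from emrcost.records import ColumnSpec, FeatureMatrix, Schema


@pytest.fixture
def mixed_schema():
    """A small mixed-kind schema: one numeric, one binary, one 3-level degree."""
    return Schema(
        columns=(
            ColumnSpec("age", "numeric"),
            ColumnSpec("smoking", "binary"),
            ColumnSpec("distension", "degree", levels=("mild", "moderate", "severe")),
        ),
        scheme_labels=("a", "b"),
    )


def make_matrix(values, kinds=None, cost=None, scheme=None, names=None):
    """Build a FeatureMatrix from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    names = names or [f"v{j}" for j in range(p)]
    kinds = kinds or ["numeric"] * p
    cols = tuple(
        ColumnSpec(n, k, levels=("l1", "l2", "l3") if k == "degree" else None)
        for n, k in zip(names, kinds)
    )
    return FeatureMatrix(
        X=pd.DataFrame(values, columns=names),
        columns=cols,
        scheme=None if scheme is None else pd.Series(scheme, dtype=object),
        cost=None if cost is None else pd.Series(np.asarray(cost, dtype=float)),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
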