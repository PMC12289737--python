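import numpy as np
import pandas as pd
import pytest

from mirmint.mirna_de import CtMatrix
from mirmint.mrna_de import ExpressionMatrix

GROUPS_3V3 = ["control"] * 3 + ["case"] * 3


def make_ct(values, groups=None, ceiling=40.0, ids=None) -> CtMatrix:
    """CtMatrix from a 2-D array-like (features x samples)."""
    arr = np.asarray(values, dtype=float)
    groups = groups or GROUPS_3V3[: arr.shape[1]]
    ids = ids or [f"m{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    return CtMatrix(
        pd.DataFrame(arr, index=ids, columns=cols),
        pd.Series(groups, index=cols),
        ceiling=ceiling,
    )


def make_expr(values, flags=None, groups=None, ids=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    groups = groups or GROUPS_3V3[: arr.shape[1]]
    ids = ids or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    vals = pd.DataFrame(arr, index=ids, columns=cols)
    if flags is None:
        fdf = pd.DataFrame("P", index=ids, columns=cols)
    else:
        fdf = pd.DataFrame(np.asarray(flags, dtype=object), index=ids, columns=cols)
    return ExpressionMatrix(vals, fdf, pd.Series(groups, index=cols))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
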