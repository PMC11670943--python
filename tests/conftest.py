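"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from songdiv import FeatureTable


def make_table(columns: dict, taxa=None, ids=None, lat=None, lon=None) -> FeatureTable:
    """Build a FeatureTable from {code: values}; None cells are missing."""
    n = len(next(iter(columns.values())))
    ids = ids or [f"r{i}" for i in range(n)]
    values = pd.DataFrame(
        {
            code: [np.nan if v is None else v for v in vals]
            for code, vals in columns.items()
        },
        index=ids,
    )
    meta = pd.DataFrame(index=values.index)
    meta["taxon"] = list(taxa) if taxa is not None else "east"
    if lat is not None:
        meta["latitude"] = lat
    if lon is not None:
        meta["longitude"] = lon
    return FeatureTable(values, meta)


#: pool of valid codes used by the random-table builders (one categorical)
NUMERIC_POOL = ["1", "2", "7", "1a", "2a", "3a", "4a", "1b", "2b", "3b", "4b", "5a"]
CATEGORICAL_POOL = ["8a", "8b"]


def random_mixed_table(
    rng: np.random.Generator,
    n: int,
    k: int,
    missing_rate: float = 0.0,
    categorical_missing: bool = True,
) -> FeatureTable:
    """Random mixed numeric/categorical table with cell-wise missingness."""
    n_cat = min(rng.integers(0, 2) + (k > 3), len(CATEGORICAL_POOL))
    n_num = k - n_cat
    codes = list(rng.choice(NUMERIC_POOL, size=n_num, replace=False))
    cat_codes = list(rng.choice(CATEGORICAL_POOL, size=n_cat, replace=False))
    cols: dict = {}
    for c in codes:
        scale = rng.uniform(0.5, 100.0)
        cols[c] = np.round(rng.random(n) * scale, 6)
    for c in cat_codes:
        cols[c] = rng.choice(["U", "D"], size=n).astype(object)
    table = make_table(cols, taxa=rng.choice(["east", "west"], size=n))
    if missing_rate > 0:
        for c in table.codes:
            if not categorical_missing and c in cat_codes:
                continue
            drop = rng.random(n) < missing_rate
            # keep at least one observed cell per column
            if drop.all():
                drop[rng.integers(n)] = False
            col = table.values[c].copy()
            col[drop] = np.nan
            table.values[c] = col
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
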