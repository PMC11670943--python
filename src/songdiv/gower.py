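"""Gower dissimilarity for mixed-type tables with pairwise missing-data omission.

For two individuals the dissimilarity is the mean, over features observed
in *both*, of per-feature terms: range-normalised absolute difference for
numeric features, 0/1 mismatch for categorical ones. Scores therefore live
in [0, 1]; a pair with no co-observed feature is explicitly undefined.
Numeric ranges are max - min over the exact table the matrix is built
from, so within-taxon and pooled analyses scale by their own data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, FeatureTableError

__all__ = [
    "UndefinedDissimilarityError",
    "DissimilarityMatrix",
    "gower_pair",
    "gower_matrix",
    "feature_ranges",
]


class UndefinedDissimilarityError(ValueError):
    """A dissimilarity is requested where no feature is co-observed."""


UNDEFINED = float("nan")  # explicit marker for pairs with no co-observed feature


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise Gower dissimilarities in [0, 1].

    ``values[i, j]`` is NaN only for undefined pairs (no co-observed
    feature); use :meth:`is_fully_defined` / :attr:`undefined_mask` rather
    than treating NaN as zero.
    """

    ids: tuple
    values: np.ndarray
    feature_ranges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            self.values[defined], self.values.T[defined]
        ):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def undefined_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def is_fully_defined(self) -> bool:
        return not self.undefined_mask.any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path_or_buf) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path_or_buf, na_rep="NA")

    @classmethod
    def from_csv(cls, path_or_buf) -> "DissimilarityMatrix":
        df = pd.read_csv(path_or_buf, index_col=0, keep_default_na=False,
                         na_values=["", "NA"])
        return cls(tuple(df.index), df.to_numpy(dtype=float))

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "ids": list(self.ids),
                "values": [
                    [None if np.isnan(v) else v for v in row] for row in self.values
                ],
                "feature_ranges": self.feature_ranges,
            },
            **kw,
        )


def feature_ranges(table: FeatureTable) -> dict[str, float]:
    """Observed max - min of every numeric feature in ``table``."""
    out: dict[str, float] = {}
    for code in table.numeric_codes:
        obs = table.values[code].dropna().to_numpy(dtype=float)
        out[code] = float(obs.max() - obs.min()) if obs.size else 0.0
    return out


def gower_pair(
    row_i: Sequence,
    row_j: Sequence,
    ranges: Sequence[float],
    dtypes: Sequence[str],
) -> float:
    """Gower dissimilarity between two aligned feature rows.

    ``ranges`` gives the numeric range per feature (ignored for
    categorical); zero-range numeric features are skipped entirely.
    Missing cells (None or NaN) are omitted pairwise; if nothing is
    co-observed the result is NaN (undefined).
    """
    if not (len(row_i) == len(row_j) == len(ranges) == len(dtypes)):
        raise ValueError("rows, ranges and dtypes must have equal length")
    num = 0.0
    den = 0
    for a, b, r, dt in zip(row_i, row_j, ranges, dtypes):
        if _missing(a) or _missing(b):
            continue
        if dt == "numeric":
            if r <= 0:
                continue  # constant feature: uninformative, weight 0
            num += abs(float(a) - float(b)) / r
        else:
            num += 0.0 if a == b else 1.0
        den += 1
    if den == 0:
        return UNDEFINED
    return num / den


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def gower_matrix(
    table: FeatureTable,
    ranges: Mapping[str, float] | None = None,
) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity matrix for a feature table.

    Ranges default to those of ``table`` itself; pass precomputed ranges to
    scale a subset against a pooled table.
    """
    n = table.n_individuals
    if n < 2:
        raise FeatureTableError("need at least 2 individuals for a dissimilarity matrix")
    if ranges is None:
        ranges = feature_ranges(table)

    num = np.zeros((n, n))
    den = np.zeros((n, n), dtype=int)
    for d in table.descriptors:
        col = table.values[d.code]
        if d.dtype == "numeric":
            r = ranges.get(d.code, 0.0)
            if r <= 0:
                continue
            x = col.to_numpy(dtype=float)
            obs = np.isfinite(x)
            both = np.outer(obs, obs)
            diff = np.abs(x[:, None] - x[None, :]) / r
            num += np.where(both, np.nan_to_num(diff), 0.0)
            den += both
        else:
            vals = col.to_numpy(dtype=object)
            obs = col.notna().to_numpy()
            both = np.outer(obs, obs)
            neq = (vals[:, None] != vals[None, :]).astype(float)
            num += np.where(both, neq, 0.0)
            den += both

    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    iu = np.triu_indices(n, k=1)
    if np.isnan(values[iu]).all():
        raise UndefinedDissimilarityError(
            "no pair of individuals shares an observed, informative feature"
        )
    return DissimilarityMatrix(tuple(table.ids), values, dict(ranges))
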