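"""Principal component analysis for mixed numeric/categorical tables.

The factor-analysis-of-mixed-data (FAMD / PCAmix) construction: numeric
columns are standardised to zero mean and unit population variance (1/n),
categorical columns are one-hot encoded, centred, and each level column is
scaled by 1/sqrt(level proportion); the resulting matrix is decomposed
with row weight 1/n. With only numeric columns this reduces exactly to
PCA of the correlation matrix; with a single categorical variable it
reduces to multiple correspondence analysis.

Missing data follow the mean/zero imputation rule: numeric missing cells
take the column mean of observed values, categorical missing cells
contribute an all-zero indicator row block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_io import FeatureTable

__all__ = [
    "MixedPCAError",
    "MixedPCAResult",
    "impute_for_pca",
    "famd",
    "top_loading_feature",
]


class MixedPCAError(ValueError):
    pass


def impute_for_pca(table: FeatureTable) -> FeatureTable:
    """Mean-impute numeric columns; leave categorical missing cells marked.

    Categorical missingness is handled at encoding time (an all-zero
    indicator row), so the returned table keeps the missing marker there.
    The input table is untouched.
    """
    out = table.copy()
    for code in table.numeric_codes:
        col = out.values[code]
        if col.isna().all():
            raise MixedPCAError(
                f"numeric column {code!r} is entirely missing; drop it before PCA"
            )
        out.values[code] = col.fillna(col.mean())
    return out


@dataclass
class MixedPCAResult:
    eigenvalues: np.ndarray  # descending, >= 0
    pct_variance: np.ndarray
    scores: pd.DataFrame  # individuals x PC1..PCm
    loadings: pd.DataFrame  # numeric variables x components (correlation-type)
    contributions: pd.DataFrame  # all variables x components (squared loading)
    total_inertia: float
    n_numeric: int
    categorical_levels: dict[str, list[str]]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "pct_variance": self.pct_variance.tolist(),
            "total_inertia": self.total_inertia,
            "loadings": self.loadings.round(10).to_dict(),
            "contributions": self.contributions.round(10).to_dict(),
        }


def _encode(table: FeatureTable) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Build the standardised FAMD matrix. Returns (Z_unweighted, column
    variable ids, numeric codes, categorical level map)."""
    n = table.n_individuals
    if n < 2:
        raise MixedPCAError("need at least 2 individuals")
    blocks: list[np.ndarray] = []
    col_vars: list[str] = []
    levels_map: dict[str, list[str]] = {}
    for d in table.descriptors:
        col = table.values[d.code]
        if d.dtype == "numeric":
            x = col.to_numpy(dtype=float)
            if np.isnan(x).any():
                raise MixedPCAError(
                    f"numeric column {d.code!r} has missing cells; run impute_for_pca first"
                )
            sd = x.std()  # population (1/n) standard deviation
            if sd == 0:
                raise MixedPCAError(
                    f"numeric column {d.code!r} is constant; drop it before PCA"
                )
            blocks.append(((x - x.mean()) / sd)[:, None])
            col_vars.append(d.code)
        else:
            obs = col.dropna()
            levels = sorted(set(obs))
            if len(levels) < 2 and not col.isna().any():
                raise MixedPCAError(
                    f"categorical column {d.code!r} has a single level; drop it before PCA"
                )
            levels_map[d.code] = levels
            G = np.zeros((n, len(levels)))
            for j, lev in enumerate(levels):
                G[:, j] = (col == lev).to_numpy(dtype=float)
            p = G.mean(axis=0)
            if (p == 0).any():
                raise MixedPCAError(f"empty level in categorical column {d.code!r}")
            blocks.append((G - p) / np.sqrt(p))
            col_vars.extend([d.code] * len(levels))
    if not blocks:
        raise MixedPCAError("no usable columns")
    Z = np.hstack(blocks)
    if Z.shape[1] < 2:
        raise MixedPCAError("need at least 2 encoded columns")
    numeric = [d.code for d in table.descriptors if d.dtype == "numeric"]
    return Z, col_vars, numeric, levels_map


def famd(table: FeatureTable, n_components: int | None = None) -> MixedPCAResult:
    """Fit mixed-data PCA and return scores, loadings and variance shares.

    Loadings for numeric variables are correlations between the variable
    and the component scores; for categorical variables the contribution
    table holds the summed squared level loadings. Component signs are
    fixed so that each component's largest-magnitude column loading is
    positive.
    """
    Z, col_vars, numeric, levels_map = _encode(table)
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    rank = int((s > 1e-10).sum())
    if n_components is None:
        n_components = rank
    m = min(n_components, rank)
    eigenvalues = s**2
    total_inertia = float(eigenvalues.sum())

    V = Vt.T
    col_loadings = V * s[None, :]  # encoded columns x components
    # sign convention: largest-magnitude column loading positive per component
    for k in range(col_loadings.shape[1]):
        j = int(np.argmax(np.abs(col_loadings[:, k])))
        if col_loadings[j, k] < 0:
            col_loadings[:, k] *= -1
            U[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(m)]
    scores = pd.DataFrame(
        np.sqrt(n) * U[:, :m] * s[None, :m], index=list(table.ids), columns=comp_names
    )

    col_vars_arr = np.asarray(col_vars)
    load_num = pd.DataFrame(
        np.vstack([col_loadings[col_vars_arr == c, :m][0] for c in numeric])
        if numeric
        else np.empty((0, m)),
        index=numeric,
        columns=comp_names,
    )
    var_order = [d.code for d in table.descriptors if d.code in set(col_vars)]
    contrib = pd.DataFrame(
        np.vstack(
            [
                (col_loadings[col_vars_arr == c, :m] ** 2).sum(axis=0)
                for c in var_order
            ]
        ),
        index=var_order,
        columns=comp_names,
    )
    return MixedPCAResult(
        eigenvalues=eigenvalues[:rank],
        pct_variance=100.0 * eigenvalues[:rank] / total_inertia,
        scores=scores,
        loadings=load_num,
        contributions=contrib,
        total_inertia=total_inertia,
        n_numeric=len(numeric),
        categorical_levels=levels_map,
    )


def top_loading_feature(result: MixedPCAResult, component: int = 1) -> tuple[str, float]:
    """Variable with the largest squared loading on a component (1-based).

    Ties break toward the earliest column in table order. Returns the
    variable code and its squared-loading contribution.
    """
    name = f"PC{component}"
    if name not in result.contributions.columns:
        raise MixedPCAError(
            f"component {component} out of range (1..{result.n_components})"
        )
    col = result.contributions[name]
    idx = int(np.argmax(col.to_numpy()))
    return str(col.index[idx]), float(col.iloc[idx])
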