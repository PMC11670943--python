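"""Inferential statistics for song divergence.

Covers the within/between permutation test on categorized dissimilarities,
multiple-testing adjustment, the joint-ECDF divergence score Delta-p with
per-feature Hedge's g, two-sample t-tests, and Spearman rank correlation
of divergence scores against relative mtDNA divergence times.

Delta-p: for each song feature, pool both populations' observed values and
build the joint empirical CDF; each population's coordinate on that
feature is the ECDF percentile (0-100) of its median. Delta-p is the
Euclidean distance between the two populations' percentile coordinate
vectors across all usable features — a rank-based, missingness-tolerant
multi-trait distance, invariant under monotone transforms of any feature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import FeatureTable
from .gower import DissimilarityMatrix

__all__ = [
    "DivergenceError",
    "CategorizedDissimilarities",
    "PermutationResult",
    "DeltaPResult",
    "categorize_dissimilarities",
    "permutation_test",
    "adjust_pvalues",
    "bonferroni_threshold",
    "joint_ecdf_percentile",
    "delta_p",
    "hedges_g",
    "two_sample_t",
    "spearman_correlation",
]

COMPARISONS = ("between_vs_within_east", "between_vs_within_west", "within_vs_within")


class DivergenceError(ValueError):
    pass


@dataclass
class CategorizedDissimilarities:
    """The strict upper triangle of a dissimilarity matrix split into
    within-east, within-west and between-taxa multisets."""

    label_east: str
    label_west: str
    within_east: np.ndarray
    within_west: np.ndarray
    between: np.ndarray
    pairs_within_east: list[tuple[int, int]]
    pairs_within_west: list[tuple[int, int]]
    pairs_between: list[tuple[int, int]]

    def counts(self) -> dict[str, int]:
        return {
            "within_east": len(self.within_east),
            "within_west": len(self.within_west),
            "between": len(self.between),
        }


def _binary_labels(labels: Sequence) -> tuple[np.ndarray, str, str]:
    lab = np.asarray([str(x) for x in labels])
    uniq = list(dict.fromkeys(lab))  # order of first appearance
    if len(uniq) != 2:
        raise DivergenceError(
            f"taxon labels must be binary, got {len(uniq)} distinct: {uniq[:5]}"
        )
    # 'east' before 'west' when those names are used; else first-appearance order
    if set(uniq) == {"east", "west"}:
        uniq = ["east", "west"]
    return lab, uniq[0], uniq[1]


def categorize_dissimilarities(D, labels: Sequence) -> CategorizedDissimilarities:
    """Partition all unordered pairs (i < j) into the three comparison
    categories defined by a binary taxon labelling."""
    arr = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    lab, east, west = _binary_labels(labels)
    if arr.shape[0] != lab.shape[0]:
        raise DivergenceError("label count does not match matrix size")
    iu, ju = np.triu_indices(arr.shape[0], k=1)
    vals = arr[iu, ju]
    is_e_i, is_e_j = lab[iu] == east, lab[ju] == east
    we = is_e_i & is_e_j
    ww = ~is_e_i & ~is_e_j
    bt = is_e_i != is_e_j
    return CategorizedDissimilarities(
        label_east=east,
        label_west=west,
        within_east=vals[we],
        within_west=vals[ww],
        between=vals[bt],
        pairs_within_east=list(zip(iu[we].tolist(), ju[we].tolist())),
        pairs_within_west=list(zip(iu[ww].tolist(), ju[ww].tolist())),
        pairs_between=list(zip(iu[bt].tolist(), ju[bt].tolist())),
    )


@dataclass
class PermutationResult:
    comparison: str
    observed_stat: float
    B: int
    p_raw: float
    sided: str
    seed: int | None
    p_fdr: float | None = None
    p_bonferroni: float | None = None
    n_east: int = 0
    n_west: int = 0

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "observed_stat": self.observed_stat,
            "B": self.B,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "p_bonferroni": self.p_bonferroni,
            "sided": self.sided,
            "seed": self.seed,
            "n_east": self.n_east,
            "n_west": self.n_west,
        }


def _category_mean_stats(
    D: np.ndarray, east_indicator: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean dissimilarity of the three categories for a batch of binary
    east-indicator rows, via the quadratic-form identity
    sum(within_east) = e' D e / 2."""
    E = np.atleast_2d(east_indicator).astype(float)
    ne = E.sum(axis=1)
    n = D.shape[0]
    nw = n - ne
    total = D.sum() / 2.0
    se = ((E @ D) * E).sum(axis=1) / 2.0
    W = 1.0 - E
    sw = ((W @ D) * W).sum(axis=1) / 2.0
    sb = total - se - sw
    with np.errstate(invalid="ignore", divide="ignore"):
        me = se / (ne * (ne - 1) / 2.0)
        mw = sw / (nw * (nw - 1) / 2.0)
        mb = sb / (ne * nw)
    return me, mw, mb


def permutation_test(
    D,
    labels: Sequence,
    comparison: str,
    B: int = 10_000,
    sided: str | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Monte-Carlo permutation test comparing category mean dissimilarities.

    The statistic is mean(category A) - mean(category B). The null
    distribution permutes taxon labels at the individual level (group
    sizes preserved) and re-derives the categories from the fixed matrix
    each replicate; p = (1 + #{null >= observed}) / (B + 1) for the
    one-sided 'greater' test, with |.| for the two-sided version.
    Between-vs-within comparisons default to one-sided 'greater'
    (is between-taxa dissimilarity larger than within?); the
    within-vs-within comparison defaults to two-sided.
    """
    if comparison not in COMPARISONS:
        raise DivergenceError(f"comparison must be one of {COMPARISONS}")
    if B < 99:
        raise DivergenceError("B must be at least 99")
    arr = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    if np.isnan(arr).any():
        raise DivergenceError("dissimilarity matrix has undefined entries")
    lab, east, west = _binary_labels(labels)
    e_obs = (lab == east).astype(float)
    ne, nw = int(e_obs.sum()), int((1 - e_obs).sum())
    if min(ne, nw) < 2:
        raise DivergenceError("each taxon needs >= 2 individuals")

    if sided is None:
        sided = "two_sided" if comparison == "within_vs_within" else "greater"
    if sided not in ("greater", "two_sided"):
        raise DivergenceError("sided must be 'greater' or 'two_sided'")

    def stat(me, mw, mb):
        if comparison == "between_vs_within_east":
            return mb - me
        if comparison == "between_vs_within_west":
            return mb - mw
        return me - mw

    me, mw, mb = _category_mean_stats(arr, e_obs)
    observed = float(stat(me, mw, mb)[0])

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(e_obs, (B, 1)), axis=1)
    me_p, mw_p, mb_p = _category_mean_stats(arr, perm)
    null = stat(me_p, mw_p, mb_p)
    if sided == "greater":
        exceed = int(np.count_nonzero(null >= observed - 1e-12))
    else:
        exceed = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
    p_raw = (1 + exceed) / (B + 1)
    return PermutationResult(
        comparison=comparison,
        observed_stat=observed,
        B=B,
        p_raw=p_raw,
        sided=sided,
        seed=seed,
        n_east=ne,
        n_west=nw,
    )


def adjust_pvalues(
    p_list: Sequence[float],
    method: Literal["benjamini_hochberg", "bonferroni"] = "benjamini_hochberg",
    family_size: int | None = None,
) -> list[float]:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up or
    Bonferroni). ``family_size`` lets a batch of analyses correct for a
    family larger than the list itself (e.g. 3 comparisons x 9 pairs)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise DivergenceError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise DivergenceError("p-values must lie in (0, 1]")
    m = family_size if family_size is not None else p.size
    if m < p.size:
        raise DivergenceError("family_size cannot be smaller than the list")
    if method == "bonferroni":
        return np.minimum(p * m, 1.0).tolist()
    if method == "benjamini_hochberg":
        if m == p.size:
            adj = multipletests(p, method="fdr_bh")[1]
        else:
            # BH step-up with the remaining family members treated as p = 1
            padded = np.concatenate([p, np.ones(m - p.size)])
            adj = multipletests(padded, method="fdr_bh")[1][: p.size]
        return np.asarray(adj).tolist()
    raise DivergenceError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 27) -> float:
    """Per-test significance criterion alpha / m."""
    if n_tests < 1:
        raise DivergenceError("n_tests must be positive")
    return alpha / n_tests


def joint_ecdf_percentile(pooled_values: Sequence[float], x: float) -> float:
    """Right-continuous empirical-CDF percentile 100 * #{v <= x} / N."""
    pool = np.asarray(pooled_values, dtype=float)
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise DivergenceError("empty pool for ECDF")
    if not np.isfinite(x):
        raise DivergenceError("x must be finite")
    return 100.0 * np.count_nonzero(pool <= x) / pool.size


@dataclass
class DeltaPResult:
    delta_p: float
    features_used: list[str]
    features_dropped: list[str]
    coordinates: pd.DataFrame  # features x (east, west) percentile coordinates
    hedges_g: pd.Series  # per feature (NaN when not computable)

    def to_dict(self) -> dict:
        return {
            "delta_p": self.delta_p,
            "features_used": self.features_used,
            "features_dropped": self.features_dropped,
            "coordinates": self.coordinates.round(10).to_dict(),
            "hedges_g": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.hedges_g.items()
            },
        }


def _numeric_frame(table, include_categorical: bool) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        df = table.values[table.numeric_codes].astype(float)
        if include_categorical:
            for code in table.categorical_codes:
                col = table.values[code]
                enc = col.map({"U": 0.0, "D": 1.0})
                df[code] = enc
        return df
    return pd.DataFrame(table).astype(float)


def delta_p(
    table_east,
    table_west,
    feature_subset: Sequence[str] | None = None,
    include_categorical: bool = False,
) -> DeltaPResult:
    """Joint-ECDF divergence score between two populations.

    Accepts FeatureTables or plain numeric DataFrames with matching
    columns. Categorical slur features are excluded by default (the
    metric presumes orderable values); ``include_categorical`` encodes
    them as 0/1. Features unobserved in either population are dropped
    and recorded.
    """
    A = _numeric_frame(table_east, include_categorical)
    Bf = _numeric_frame(table_west, include_categorical)
    common = [c for c in A.columns if c in set(Bf.columns)]
    if feature_subset is not None:
        common = [c for c in common if c in set(feature_subset)]
    if len(A) < 2 or len(Bf) < 2:
        raise DivergenceError("need >= 2 individuals per population")

    used, dropped, rows, gvals = [], [], [], []
    for c in common:
        a = A[c].dropna().to_numpy(dtype=float)
        b = Bf[c].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            dropped.append(c)
            continue
        pool = np.concatenate([a, b])
        pa = joint_ecdf_percentile(pool, float(np.median(a)))
        pb = joint_ecdf_percentile(pool, float(np.median(b)))
        rows.append((pa, pb))
        used.append(c)
        if a.size >= 2 and b.size >= 2 and (a.std(ddof=1) > 0 or b.std(ddof=1) > 0):
            gvals.append(hedges_g(a, b))
        else:
            gvals.append(np.nan)
    if not used:
        raise DivergenceError("no feature observed in both populations")
    coords = pd.DataFrame(rows, index=used, columns=["east", "west"])
    dp = float(np.linalg.norm(coords["east"] - coords["west"]))
    return DeltaPResult(
        delta_p=dp,
        features_used=used,
        features_dropped=dropped,
        coordinates=coords,
        hedges_g=pd.Series(gvals, index=used, dtype=float),
    )


def hedges_g(x_a: Sequence[float], x_b: Sequence[float]) -> float:
    """Bias-corrected standardised mean difference
    g = J * (mean_A - mean_B) / s_pooled, J = 1 - 3 / (4 N - 9)."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DivergenceError("need >= 2 observations per side")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise DivergenceError("zero pooled variance")
    J = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(J * (a.mean() - b.mean()) / math.sqrt(sp2))


def two_sample_t(
    x_a: Sequence[float],
    x_b: Sequence[float],
    variant: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p)."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DivergenceError("need >= 2 observations per side")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DivergenceError("zero variance on both sides")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman_correlation(
    delta_p_values: Sequence[float],
    divergence_times: Sequence[float],
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman rank correlation of divergence scores vs relative times.

    rho uses average ranks on ties. The two-sided p-value is computed by
    exact enumeration of rank permutations for n <= ``exact_max_n`` when
    there are no ties, and by the standard t approximation otherwise.
    """
    x = np.asarray(delta_p_values, dtype=float)
    y = np.asarray(divergence_times, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DivergenceError("need two equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DivergenceError("rho undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if no_ties and n <= exact_max_n:
        rx = stats.rankdata(x)
        perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
        d2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
        rho_null = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
        p = float(np.count_nonzero(np.abs(rho_null) >= abs(rho) - 1e-12) / len(perms))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
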