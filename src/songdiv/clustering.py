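"""Partitioning around medoids (PAM) on a dissimilarity matrix.

Small medoid search spaces are solved exactly by enumeration, so results
at desk scale are the true cost optimum; beyond that the classic
Kaufman-Rousseeuw BUILD + SWAP local search takes over: BUILD greedily
seeds k medoids, SWAP repeatedly applies the single best cost-reducing
(medoid, non-medoid) exchange until no exchange lowers the total
dissimilarity of individuals to their nearest medoid. All ties break
toward the lowest individual index, so results are exactly reproducible.

Also provides silhouette widths, silhouette-guided selection of k over a
scan range (k = 2-8 by default), and a cluster-vs-geography concordance
score used to decide whether acoustic clusters track locality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gower import DissimilarityMatrix, UndefinedDissimilarityError

__all__ = [
    "ClusteringError",
    "ClusteringResult",
    "KSelectionProfile",
    "ConcordanceResult",
    "pam",
    "silhouette",
    "select_k",
    "cluster_region_concordance",
]

DEFAULT_WEAK_ASW_THRESHOLD = 0.25


class ClusteringError(ValueError):
    pass


def _as_array(D) -> tuple[np.ndarray, tuple]:
    if isinstance(D, DissimilarityMatrix):
        if not D.is_fully_defined():
            raise UndefinedDissimilarityError(
                "dissimilarity matrix has undefined entries; drop individuals "
                "with no co-observed features before clustering"
            )
        return D.values, D.ids
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ClusteringError("dissimilarity matrix must be square")
    if np.isnan(arr).any():
        raise UndefinedDissimilarityError("dissimilarity matrix has undefined entries")
    return arr, tuple(range(arr.shape[0]))


@dataclass
class ClusteringResult:
    k: int
    medoid_indices: tuple[int, ...]
    medoid_ids: tuple
    assignment: np.ndarray  # cluster index (0..k-1) per individual
    total_cost: float
    silhouettes: np.ndarray | None = None
    average_silhouette_width: float | None = None
    ids: tuple = ()

    def cluster_sizes(self) -> list[int]:
        return np.bincount(self.assignment, minlength=self.k).tolist()

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "medoid_ids": [str(m) for m in self.medoid_ids],
            "assignment": {str(i): int(a) for i, a in zip(self.ids, self.assignment)},
            "total_cost": self.total_cost,
            "average_silhouette_width": self.average_silhouette_width,
            "cluster_sizes": self.cluster_sizes(),
        }


def _cost(D: np.ndarray, medoids: Sequence[int]) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def _assign(D: np.ndarray, medoids: Sequence[int]) -> np.ndarray:
    # nearest medoid; ties resolve to the lowest medoid index via argmin
    sub = D[:, list(medoids)]
    assignment = np.argmin(sub, axis=1)
    for c, m in enumerate(medoids):
        assignment[m] = c  # a medoid always belongs to itself
    return assignment


#: exact enumeration is used when C(n, k) does not exceed this
EXACT_SEARCH_CAP = 10_000


def pam(
    D, k: int, max_swap_iter: int = 200, exact_cap: int = EXACT_SEARCH_CAP
) -> ClusteringResult:
    """k-medoids clustering.

    Small search spaces (C(n, k) <= ``exact_cap``) are solved exactly by
    enumerating medoid subsets; larger ones use the classic BUILD + SWAP
    local search. Both are deterministic: ties resolve to the
    lexicographically smallest medoid set. Requires a fully defined
    dissimilarity matrix and 1 <= k < n; k = 1 returns the single medoid
    minimising its row sum.
    """
    arr, ids = _as_array(D)
    n = arr.shape[0]
    if not 1 <= k < n:
        raise ClusteringError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")

    if math.comb(n, k) <= exact_cap:
        best_cost = np.inf
        best_medoids: tuple[int, ...] | None = None
        for combo in combinations(range(n), k):
            c = _cost(arr, combo)
            if c < best_cost - 1e-12:
                best_cost = c
                best_medoids = combo
        return _finalize(arr, ids, list(best_medoids), k)

    # BUILD: first medoid minimises total dissimilarity; subsequent medoids
    # maximise the total decrease in nearest-medoid distance.
    medoids = [int(np.argmin(arr.sum(axis=1)))]
    while len(medoids) < k:
        nearest = arr[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - arr, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    cost = _cost(arr, medoids)
    for _ in range(max_swap_iter):
        best = None  # (cost, medoid_pos, h)
        for pos in range(len(medoids)):
            trial = list(medoids)
            for h in range(n):
                if h in medoids:
                    continue
                trial[pos] = h
                c = _cost(arr, trial)
                if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                    best = (c, pos, h)
            trial[pos] = medoids[pos]
        if best is None:
            break
        cost, pos, h = best
        medoids[pos] = h

    return _finalize(arr, ids, medoids, k)


def _finalize(arr: np.ndarray, ids: tuple, medoids: list[int], k: int) -> ClusteringResult:
    medoids = sorted(medoids)
    assignment = _assign(arr, medoids)
    result = ClusteringResult(
        k=k,
        medoid_indices=tuple(medoids),
        medoid_ids=tuple(ids[m] for m in medoids),
        assignment=assignment,
        total_cost=_cost(arr, medoids),
        ids=ids,
    )
    if k >= 2:
        s, asw = silhouette(arr, assignment)
        result.silhouettes = s
        result.average_silhouette_width = asw
    return result


def silhouette(D, assignment: Sequence[int]) -> tuple[np.ndarray, float]:
    """Per-individual silhouette widths s(i) and their average.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean dissimilarity
    to the individual's own cluster (self excluded) and b(i) the smallest
    mean dissimilarity to any other cluster. Singletons get s(i) = 0, as
    does the degenerate a = b = 0 tie.
    """
    arr, _ = _as_array(D)
    assignment = np.asarray(assignment, dtype=int)
    labels = np.unique(assignment)
    if labels.size < 2:
        raise ClusteringError("silhouette is undefined for a single cluster")
    n = arr.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = assignment == assignment[i]
        own_size = own.sum()
        if own_size == 1:
            s[i] = 0.0
            continue
        a = arr[i, own].sum() / (own_size - 1)
        b = min(
            arr[i, assignment == lab].mean() for lab in labels if lab != assignment[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


@dataclass
class KSelectionProfile:
    asw_by_k: dict[int, float]
    selected_k: int
    weak_structure_flag: bool
    weak_asw_threshold: float
    clusterings: dict[int, ClusteringResult] = field(default_factory=dict)

    @property
    def best_clustering(self) -> ClusteringResult:
        """Clustering at the selected k, or at the best scanned k when the
        weak-structure rule reported k = 1."""
        k = self.selected_k if self.selected_k in self.clusterings else max(
            self.asw_by_k, key=lambda k: (self.asw_by_k[k], -k)
        )
        return self.clusterings[k]

    def to_dict(self) -> dict:
        return {
            "asw_by_k": {str(k): v for k, v in self.asw_by_k.items()},
            "selected_k": self.selected_k,
            "weak_structure_flag": self.weak_structure_flag,
            "weak_asw_threshold": self.weak_asw_threshold,
        }


def select_k(
    D,
    k_min: int = 2,
    k_max: int = 8,
    weak_asw_threshold: float = DEFAULT_WEAK_ASW_THRESHOLD,
) -> KSelectionProfile:
    """Scan k over [k_min, k_max], pick the k with the highest average
    silhouette width.

    The scan is truncated to k < n. When even the best average silhouette
    width falls below ``weak_asw_threshold`` the data show no usable
    cluster structure and the profile reports k = 1 with
    ``weak_structure_flag`` set.
    """
    arr, _ = _as_array(D)
    n = arr.shape[0]
    ks = [k for k in range(k_min, k_max + 1) if k < n]
    if not ks:
        raise ClusteringError(f"no feasible k in [{k_min}, {k_max}] for n={n}")
    asw_by_k: dict[int, float] = {}
    clusterings: dict[int, ClusteringResult] = {}
    for k in ks:
        res = pam(D, k)
        clusterings[k] = res
        asw_by_k[k] = res.average_silhouette_width
    best_k = max(asw_by_k, key=lambda k: (asw_by_k[k], -k))
    weak = asw_by_k[best_k] < weak_asw_threshold
    return KSelectionProfile(
        asw_by_k=asw_by_k,
        selected_k=1 if weak else best_k,
        weak_structure_flag=weak,
        weak_asw_threshold=weak_asw_threshold,
        clusterings=clusterings,
    )


@dataclass
class ConcordanceResult:
    contingency: pd.DataFrame  # clusters x regions
    agreement: float
    mapping: dict  # cluster label -> region label for matched clusters

    def to_dict(self) -> dict:
        return {
            "contingency": {
                str(c): {str(r): int(v) for r, v in row.items()}
                for c, row in self.contingency.iterrows()
            },
            "agreement": self.agreement,
            "mapping": {str(k): str(v) for k, v in self.mapping.items()},
        }


def cluster_region_concordance(
    assignment: Sequence, region_labels: Sequence
) -> ConcordanceResult:
    """Best-matching agreement between cluster assignments and regions.

    Maximises, over one-to-one matchings of clusters to regions, the
    fraction of individuals whose cluster is matched to their region.
    Invariant under renaming of either labelling.
    """
    assignment = np.asarray(assignment)
    regions = np.asarray(region_labels)
    if assignment.shape[0] != regions.shape[0]:
        raise ClusteringError("assignment and region labels differ in length")
    if np.unique(regions).size < 2:
        raise ClusteringError("need at least 2 regions for concordance")
    tab = pd.crosstab(pd.Series(assignment, name="cluster"),
                      pd.Series(regions, name="region"))
    rows, cols = linear_sum_assignment(tab.to_numpy(), maximize=True)
    matched = int(tab.to_numpy()[rows, cols].sum())
    mapping = {tab.index[r]: tab.columns[c] for r, c in zip(rows, cols)}
    return ConcordanceResult(tab, matched / assignment.shape[0], mapping)
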