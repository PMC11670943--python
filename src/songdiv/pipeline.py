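"""End-to-end orchestration of the two analysis scales.

``run_pair_analysis`` performs the full between-taxa comparison for one
east/west pair: Gower dissimilarities on the pooled table, silhouette-
guided PAM, mixed-data PCA, the three within/between permutation tests
with BH-FDR and Bonferroni adjustment, the Delta-p divergence score, and
cluster-vs-taxon concordance. ``run_within_taxon_analysis`` screens a
single taxon for localized song variants: clustering, top-loading
feature, a t-test between clusters on that feature, and concordance of
clusters with a candidate geographic region. A variant is called only
when (1) clustering structure is real (k >= 2, not weak) and (2) the
clusters track geography above a configurable agreement threshold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusteringResult,
    ConcordanceResult,
    KSelectionProfile,
    cluster_region_concordance,
    select_k,
)
from .divergence import (
    COMPARISONS,
    DeltaPResult,
    DivergenceError,
    PermutationResult,
    adjust_pvalues,
    delta_p,
    permutation_test,
    two_sample_t,
)
from .feature_io import FeatureTable, FeatureTableError, require_min_group_sizes
from .gower import gower_matrix
from .mixed_pca import MixedPCAResult, famd, impute_for_pca, top_loading_feature

__all__ = [
    "PairAnalysisConfig",
    "WithinAnalysisConfig",
    "PairReport",
    "WithinReport",
    "run_pair_analysis",
    "run_pair_batch",
    "run_within_taxon_analysis",
]


@dataclass(frozen=True)
class PairAnalysisConfig:
    k_min: int = 2
    k_max: int = 8
    weak_asw_threshold: float = 0.25
    permutation_B: int = 10_000
    seed: int = 0
    n_components: int = 6
    include_categorical_in_deltap: bool = False
    #: Bonferroni family size; a batch of m pair analyses uses 3 * m
    bonferroni_family: int = 3


@dataclass(frozen=True)
class WithinAnalysisConfig:
    k_min: int = 2
    k_max: int = 8
    weak_asw_threshold: float = 0.25
    concordance_threshold: float = 0.8
    n_components: int = 6
    #: (lon_min, lon_max, lat_min, lat_max) defining the candidate region
    region_box: tuple[float, float, float, float] | None = None
    #: alternatively, a metadata column holding region labels
    region_column: str | None = None
    t_variant: str = "pooled"
    seed: int = 0


def _drop_degenerate_for_pca(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Drop columns mixed-data PCA cannot use: all-missing columns,
    constant numeric columns, and complete single-level categoricals."""
    drop: list[str] = []
    for d in table.descriptors:
        col = table.values[d.code]
        obs = col.dropna()
        if obs.empty:
            drop.append(d.code)
        elif d.dtype == "numeric" and obs.nunique() == 1:
            drop.append(d.code)
        elif d.dtype == "categorical" and obs.nunique() == 1 and not col.isna().any():
            drop.append(d.code)
    if drop:
        keep = [c for c in table.codes if c not in set(drop)]
        return table.subset_features(keep), drop
    return table, drop


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PairReport:
    n_east: int
    n_west: int
    features_shared: list[str]
    features_dropped_east: list[str]
    features_dropped_west: list[str]
    individuals_dropped: list
    gower_summary: dict
    k_profile: KSelectionProfile
    clustering: ClusteringResult
    pca: MixedPCAResult
    permutations: dict[str, PermutationResult]
    delta_p_result: DeltaPResult
    taxon_concordance: ConcordanceResult
    concordance_at_k: int
    seed: int
    bonferroni_family: int
    version: str = __version__
    stage_hashes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "n_east": self.n_east,
                "n_west": self.n_west,
                "n_features": len(self.features_shared),
                "features_shared": self.features_shared,
                "features_dropped_east": self.features_dropped_east,
                "features_dropped_west": self.features_dropped_west,
                "individuals_dropped": [str(i) for i in self.individuals_dropped],
            },
            "gower": self.gower_summary,
            "k_selection": self.k_profile.to_dict(),
            "clustering": self.clustering.to_dict(),
            "pca": {
                "pc1_pct": float(self.pca.pct_variance[0]),
                "pc2_pct": float(self.pca.pct_variance[1])
                if len(self.pca.pct_variance) > 1
                else None,
                "eigenvalues": self.pca.eigenvalues[: self.pca.n_components].tolist(),
                "total_inertia": self.pca.total_inertia,
            },
            "permutations": {k: v.to_dict() for k, v in self.permutations.items()},
            "delta_p": self.delta_p_result.to_dict(),
            "taxon_concordance": self.taxon_concordance.to_dict(),
            "concordance_at_k": self.concordance_at_k,
            "seed": self.seed,
            "bonferroni_family": self.bonferroni_family,
            "version": self.version,
            "stage_hashes": self.stage_hashes,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary_row(self) -> dict:
        """Flat summary mimicking a per-pair results-table row."""
        d = self.to_dict()
        return {
            "PC1_pct": d["pca"]["pc1_pct"],
            "PC2_pct": d["pca"]["pc2_pct"],
            "k": self.k_profile.selected_k,
            "delta_p": self.delta_p_result.delta_p,
            "taxon_concordance": self.taxon_concordance.agreement,
            "p_between_vs_within_east": self.permutations[
                "between_vs_within_east"
            ].p_raw,
            "p_between_vs_within_west": self.permutations[
                "between_vs_within_west"
            ].p_raw,
        }


def _reconcile(east: FeatureTable, west: FeatureTable):
    shared = [c for c in east.codes if c in set(west.codes)]
    if not shared:
        raise FeatureTableError("east and west tables share no measurement codes")
    dropped_e = [c for c in east.codes if c not in set(shared)]
    dropped_w = [c for c in west.codes if c not in set(shared)]
    return east.subset_features(shared), west.subset_features(shared), shared, dropped_e, dropped_w


def run_pair_analysis(
    east: FeatureTable, west: FeatureTable, config: PairAnalysisConfig | None = None
) -> PairReport:
    """Full between-taxa analysis of one east/west pair."""
    cfg = config or PairAnalysisConfig()
    east_r, west_r, shared, dropped_e, dropped_w = _reconcile(east, west)
    pooled = FeatureTable.concat([east_r, west_r])
    require_min_group_sizes(pooled, 2)

    D = gower_matrix(pooled)
    # drop individuals with any undefined pairwise dissimilarity
    dropped_ids: list = []
    if not D.is_fully_defined():
        bad = np.where(np.isnan(D.values).any(axis=1))[0]
        dropped_ids = [D.ids[i] for i in bad]
        keep = [i for i in pooled.ids if i not in set(dropped_ids)]
        pooled = pooled.subset_individuals(keep)
        require_min_group_sizes(pooled, 2)
        D = gower_matrix(pooled)
    iu = np.triu_indices(D.n, k=1)
    gower_summary = {
        "n": D.n,
        "mean": float(np.mean(D.values[iu])),
        "max": float(np.max(D.values[iu])),
    }

    profile = select_k(D, cfg.k_min, cfg.k_max, cfg.weak_asw_threshold)
    clustering = profile.best_clustering

    pca_table, pca_dropped = _drop_degenerate_for_pca(pooled)
    pca = famd(impute_for_pca(pca_table), n_components=cfg.n_components)

    labels = pooled.taxon_labels.to_numpy()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(COMPARISONS))
    permutations: dict[str, PermutationResult] = {}
    for comparison, s in zip(COMPARISONS, seeds):
        permutations[comparison] = permutation_test(
            D, labels, comparison, B=cfg.permutation_B, seed=int(s % 2**31)
        )
    raw = [permutations[c].p_raw for c in COMPARISONS]
    fdr = adjust_pvalues(raw, "benjamini_hochberg")
    bon = adjust_pvalues(raw, "bonferroni", family_size=cfg.bonferroni_family)
    for c, pf, pb in zip(COMPARISONS, fdr, bon):
        permutations[c].p_fdr = pf
        permutations[c].p_bonferroni = pb

    east_final = pooled.subset_individuals(
        [i for i, t in pooled.taxon_labels.items() if t == labels_first(labels)]
    )
    west_final = pooled.subset_individuals(
        [i for i, t in pooled.taxon_labels.items() if t != labels_first(labels)]
    )
    dp = delta_p(
        east_final,
        west_final,
        include_categorical=cfg.include_categorical_in_deltap,
    )

    concordance = cluster_region_concordance(clustering.assignment, labels)

    report = PairReport(
        n_east=east_final.n_individuals,
        n_west=west_final.n_individuals,
        features_shared=shared,
        features_dropped_east=dropped_e,
        features_dropped_west=dropped_w,
        individuals_dropped=dropped_ids,
        gower_summary=gower_summary,
        k_profile=profile,
        clustering=clustering,
        pca=pca,
        permutations=permutations,
        delta_p_result=dp,
        taxon_concordance=concordance,
        concordance_at_k=clustering.k,
        seed=cfg.seed,
        bonferroni_family=cfg.bonferroni_family,
    )
    # hash-chain the stages for provenance
    h = _digest({"n_east": report.n_east, "n_west": report.n_west, "codes": shared})
    for stage, payload in [
        ("inputs", None),
        ("gower", gower_summary),
        ("k_selection", profile.to_dict()),
        ("pca", {"eig": pca.eigenvalues.tolist()}),
        ("permutations", {k: v.to_dict() for k, v in permutations.items()}),
        ("delta_p", dp.to_dict()),
    ]:
        h = _digest({"prev": h, "stage": stage, "payload": payload})
        report.stage_hashes[stage] = h
    return report


def labels_first(labels: Sequence) -> str:
    """Canonical first taxon label: 'east' when present, else first seen."""
    uniq = list(dict.fromkeys(str(x) for x in labels))
    return "east" if "east" in uniq else uniq[0]


def run_pair_batch(
    pairs: Sequence[tuple[FeatureTable, FeatureTable]],
    config: PairAnalysisConfig | None = None,
) -> list[PairReport]:
    """Analyse several pairs, correcting over the full 3 x m test family."""
    cfg = config or PairAnalysisConfig()
    family = 3 * len(pairs)
    reports = []
    for i, (east, west) in enumerate(pairs):
        sub = PairAnalysisConfig(
            **{
                **cfg.__dict__,
                "bonferroni_family": family,
                "seed": int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % 2**31),
            }
        )
        reports.append(run_pair_analysis(east, west, sub))
    all_raw = [r.permutations[c].p_raw for r in reports for c in COMPARISONS]
    fdr = adjust_pvalues(all_raw, "benjamini_hochberg")
    bon = adjust_pvalues(all_raw, "bonferroni")
    i = 0
    for r in reports:
        for c in COMPARISONS:
            r.permutations[c].p_fdr = fdr[i]
            r.permutations[c].p_bonferroni = bon[i]
            i += 1
    return reports


@dataclass
class WithinReport:
    n_individuals: int
    k_profile: KSelectionProfile
    pca: MixedPCAResult
    top_feature: str
    top_feature_contribution: float
    t_statistic: float | None
    t_df: float | None
    t_pvalue: float | None
    concordance: ConcordanceResult | None
    concordance_evaluated: bool
    variant_call: bool
    config: WithinAnalysisConfig

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "k_selection": self.k_profile.to_dict(),
            "pca": {
                "pc1_pct": float(self.pca.pct_variance[0]),
                "pc2_pct": float(self.pca.pct_variance[1])
                if len(self.pca.pct_variance) > 1
                else None,
            },
            "top_loading_feature": self.top_feature,
            "top_feature_contribution": self.top_feature_contribution,
            "t_test": {
                "t": self.t_statistic,
                "df": self.t_df,
                "p": self.t_pvalue,
            },
            "concordance": self.concordance.to_dict() if self.concordance else None,
            "concordance_evaluated": self.concordance_evaluated,
            "variant_call": self.variant_call,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def run_within_taxon_analysis(
    table: FeatureTable, config: WithinAnalysisConfig | None = None
) -> WithinReport:
    """Screen one taxon for a localized song variant."""
    cfg = config or WithinAnalysisConfig()
    if table.n_individuals < 2 * cfg.k_min:
        raise FeatureTableError(
            f"need at least {2 * cfg.k_min} individuals for the within-taxon screen"
        )
    D = gower_matrix(table)
    working = table
    if not D.is_fully_defined():
        bad = np.where(np.isnan(D.values).any(axis=1))[0]
        keep = [i for j, i in enumerate(working.ids) if j not in set(bad.tolist())]
        working = working.subset_individuals(keep)
        D = gower_matrix(working)

    profile = select_k(D, cfg.k_min, cfg.k_max, cfg.weak_asw_threshold)
    clustering = profile.best_clustering
    pca_table, _ = _drop_degenerate_for_pca(working)
    pca = famd(impute_for_pca(pca_table), n_components=cfg.n_components)
    top_feature, contribution = top_loading_feature(pca, 1)

    # t-test on the top-loading feature between the two largest clusters
    t_stat = t_df = t_p = None
    sizes = np.asarray(clustering.cluster_sizes())
    if profile.selected_k >= 2 and top_feature in working.numeric_codes:
        big2 = np.argsort(sizes, kind="stable")[::-1][:2]
        x = working.values[top_feature].to_numpy(dtype=float)
        ga = x[(clustering.assignment == big2[0]) & np.isfinite(x)]
        gb = x[(clustering.assignment == big2[1]) & np.isfinite(x)]
        if ga.size >= 2 and gb.size >= 2:
            try:
                t_stat, t_df, t_p = two_sample_t(ga, gb, cfg.t_variant)
            except DivergenceError:
                pass

    concordance = None
    evaluated = False
    if cfg.region_column is not None or cfg.region_box is not None:
        if cfg.region_column is not None:
            if cfg.region_column not in working.meta.columns:
                raise FeatureTableError(
                    f"metadata has no region column {cfg.region_column!r}"
                )
            regions = working.meta[cfg.region_column].astype(str).to_numpy()
        else:
            if not working.has_coordinates():
                raise FeatureTableError(
                    "concordance with a region box requires latitude/longitude metadata"
                )
            lon = working.meta["longitude"].to_numpy(dtype=float)
            lat = working.meta["latitude"].to_numpy(dtype=float)
            lon_min, lon_max, lat_min, lat_max = cfg.region_box
            inside = (
                (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
            )
            regions = np.where(inside, "inside", "outside")
        if np.unique(regions).size >= 2:
            concordance = cluster_region_concordance(clustering.assignment, regions)
            evaluated = True

    variant_call = bool(
        profile.selected_k >= 2
        and not profile.weak_structure_flag
        and evaluated
        and concordance.agreement >= cfg.concordance_threshold
    )
    return WithinReport(
        n_individuals=working.n_individuals,
        k_profile=profile,
        pca=pca,
        top_feature=top_feature,
        top_feature_contribution=contribution,
        t_statistic=t_stat,
        t_df=t_df,
        t_pvalue=t_p,
        concordance=concordance,
        concordance_evaluated=evaluated,
        variant_call=variant_call,
        config=cfg,
    )
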