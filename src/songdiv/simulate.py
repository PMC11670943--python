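"""Synthetic song-feature tables with the statistical structure the
analysis pipeline assumes.

Each simulated pair consists of an eastern and a western population
sharing one measurement schema: song duration, syllable count, a slur
direction, per-syllable durations / peak / minimum / maximum frequencies
and a repeat count. Durations are log-normal, frequencies normal, counts
Poisson, slur Bernoulli over {U, D}. East-west divergence is injected as
per-feature location shifts expressed in within-population standard
deviations. Missingness is structural: each syllable beyond the first two
is present with a configurable probability, and an absent syllable blanks
every one of its measurement codes at once (the syllable count tracks the
realised structure). Localities are drawn from two 2-D Gaussian regions.

One global seed fans out to per-feature substreams keyed by the
measurement code, so adding or removing features does not shift the draws
of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, parse_measurement_code

__all__ = [
    "PairSimConfig",
    "generate_pair",
    "generate_taxon",
    "inject_local_variant",
    "generate_divergence_table",
]


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Independent substream keyed by strings; stable across runs."""
    entropy = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class PairSimConfig:
    """Study conditions for one simulated east/west pair.

    Defaults give n = 50 individuals per taxon and K = 20 features
    (mid-range of the study design: 25-75 individuals, 16-42 features).
    ``effect_sd`` shifts ``affected_features`` in the western population by
    that many within-population standard deviations.
    """

    n_east: int = 50
    n_west: int = 50
    syllables: tuple[str, ...] = ("a", "b", "c", "d")
    #: probability that an individual's song contains each syllable
    syllable_presence: Mapping[str, float] = field(
        default_factory=lambda: {"a": 1.0, "b": 1.0, "c": 0.9, "d": 0.75}
    )
    include_song_duration: bool = True
    include_syllable_count: bool = True
    include_slur: bool = True
    include_repeat_count: bool = True
    effect_sd: float = 0.0
    #: None -> default subset of 5 frequency features
    affected_features: tuple[str, ...] | None = None
    #: probability of an up-slurred song, east / west; slur direction is
    #: taxon-typical in oscines, so the default is consistent (0.9) rather
    #: than a per-individual coin flip, and identical across taxa
    slur_p_east: float = 0.9
    slur_p_west: float = 0.9
    #: additional cell-wise missingness on numeric features (MCAR)
    mcar_rate: float = 0.0
    east_centroid: tuple[float, float] = (-78.0, 43.0)  # (lon, lat)
    west_centroid: tuple[float, float] = (-118.0, 46.0)
    locality_sd_deg: float = 3.0
    seed: int = 0

    def feature_codes(self) -> list[str]:
        codes: list[str] = []
        if self.include_song_duration:
            codes.append("1")
        if self.include_syllable_count:
            codes.append("7")
        if self.include_slur:
            codes.append(f"8{self.syllables[0]}")
        if self.include_repeat_count:
            codes.append(f"5{self.syllables[0]}")
        for s in self.syllables:
            codes.extend([f"1{s}", f"2{s}", f"3{s}", f"4{s}"])
        return codes

    def default_affected(self) -> tuple[str, ...]:
        if self.affected_features is not None:
            return self.affected_features
        freq = [c for c in self.feature_codes() if c[0] in "234"]
        return tuple(freq[:5])


def _feature_params(cfg: PairSimConfig) -> dict[str, dict]:
    """Per-feature base-distribution parameters, drawn once from
    code-keyed substreams so they are shared by both populations."""
    params: dict[str, dict] = {}
    for code in cfg.feature_codes():
        d = parse_measurement_code(code)
        rng = _stream(cfg.seed, "params", code)
        if d.quantity == "duration_s":
            median = rng.uniform(0.1, 2.0)
            params[code] = {"kind": "lognormal", "mu": np.log(median), "sigma": 0.3}
        elif d.quantity in ("peak_freq_hz", "min_freq_hz", "max_freq_hz"):
            center = rng.uniform(2000.0, 9000.0)
            offset = {"min_freq_hz": -600.0, "max_freq_hz": 600.0}.get(d.quantity, 0.0)
            params[code] = {
                "kind": "normal",
                "mean": center + offset,
                "sd": rng.uniform(200.0, 800.0),
            }
        elif d.quantity == "n_repeats":
            params[code] = {"kind": "poisson", "lam": rng.uniform(1.0, 10.0)}
        elif d.quantity == "n_syllables":
            params[code] = {"kind": "syllable_count"}
        elif d.quantity == "slur":
            params[code] = {"kind": "slur"}
        else:
            params[code] = {"kind": "normal", "mean": 50.0, "sd": 15.0}
    return params


def generate_taxon(
    cfg: PairSimConfig,
    side: str,
    params: dict[str, dict] | None = None,
) -> FeatureTable:
    """Simulate one taxon ('east' or 'west') under the pair configuration."""
    if side not in ("east", "west"):
        raise ValueError("side must be 'east' or 'west'")
    n = cfg.n_east if side == "east" else cfg.n_west
    if n < 2:
        raise ValueError("need at least 2 individuals per taxon")
    codes = cfg.feature_codes()
    if not codes:
        raise ValueError("infeasible config: no features")
    if params is None:
        params = _feature_params(cfg)
    affected = set(cfg.default_affected()) if side == "west" else set()
    shift = cfg.effect_sd

    # structural missingness: syllable presence per individual
    present: dict[str, np.ndarray] = {}
    for s in cfg.syllables:
        p = float(cfg.syllable_presence.get(s, 1.0))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid presence probability for syllable {s!r}")
        rng = _stream(cfg.seed, "presence", side, s)
        present[s] = rng.random(n) < p
    n_syll = np.sum([present[s] for s in cfg.syllables], axis=0).astype(float)

    data: dict[str, np.ndarray] = {}
    for code in codes:
        d = parse_measurement_code(code)
        rng = _stream(cfg.seed, "values", side, code)
        p = params[code]
        if p["kind"] == "lognormal":
            z = rng.standard_normal(n)
            if code in affected:
                z = z + shift
            x = np.exp(p["mu"] + p["sigma"] * z)
        elif p["kind"] == "normal":
            x = p["mean"] + p["sd"] * rng.standard_normal(n)
            if code in affected:
                x = x + shift * p["sd"]
        elif p["kind"] == "poisson":
            lam = p["lam"]
            if code in affected:
                lam = max(lam + shift * np.sqrt(lam), 0.05)
            x = rng.poisson(lam, size=n).astype(float)
        elif p["kind"] == "syllable_count":
            x = n_syll.copy()
        else:  # slur
            p_up = cfg.slur_p_east if side == "east" else cfg.slur_p_west
            x = np.where(rng.random(n) < p_up, "U", "D").astype(object)
        if d.syllable is not None and d.syllable in present:
            mask = ~present[d.syllable]
            if d.dtype == "numeric":
                x = np.where(mask, np.nan, x.astype(float))
            else:
                x = x.copy()
                x[mask] = np.nan
        if cfg.mcar_rate > 0 and d.dtype == "numeric":
            drop = _stream(cfg.seed, "mcar", side, code).random(n) < cfg.mcar_rate
            x = np.where(drop, np.nan, x)
        data[code] = x

    loc_rng = _stream(cfg.seed, "locality", side)
    cx, cy = cfg.east_centroid if side == "east" else cfg.west_centroid
    lon = cx + cfg.locality_sd_deg * loc_rng.standard_normal(n)
    lat = cy + cfg.locality_sd_deg * loc_rng.standard_normal(n)

    ids = [f"{side[0].upper()}{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(data, index=ids)[codes]
    meta = pd.DataFrame(
        {"taxon": side, "latitude": lat, "longitude": lon}, index=ids
    )
    return FeatureTable(values, meta)


def generate_pair(cfg: PairSimConfig) -> tuple[FeatureTable, FeatureTable]:
    """Simulate an east/west pair sharing one schema and base parameters."""
    params = _feature_params(cfg)
    return generate_taxon(cfg, "east", params), generate_taxon(cfg, "west", params)


def inject_local_variant(
    table: FeatureTable,
    feature_code: str,
    shift_sd: float,
    fraction: float | None = 0.25,
    region_box: tuple[float, float, float, float] | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Shift one numeric feature for a localized subset of individuals.

    The subset is either the individuals inside ``region_box``
    (lon_min, lon_max, lat_min, lat_max), or — when the table has
    coordinates — the requested ``fraction`` with the lowest longitude (a
    geographically contiguous cluster), or a random fraction if no
    localities exist. Injected rows are flagged in ``meta['variant_flag']``
    and the realised bounding box is stored in ``attrs['variant_region_box']``.
    """
    d = parse_measurement_code(feature_code)
    if d.dtype != "numeric":
        raise ValueError("cannot inject a shift into a categorical feature")
    if feature_code not in table.codes:
        raise ValueError(f"feature {feature_code!r} not in table")
    out = table.copy()
    n = out.n_individuals
    if region_box is not None:
        lon = out.meta["longitude"].to_numpy(dtype=float)
        lat = out.meta["latitude"].to_numpy(dtype=float)
        lon_min, lon_max, lat_min, lat_max = region_box
        sel = (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
    else:
        if fraction is None or not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1) when no region_box is given")
        m = max(2, int(round(fraction * n)))
        if table.has_coordinates():
            order = np.argsort(out.meta["longitude"].to_numpy(dtype=float),
                               kind="stable")
            sel = np.zeros(n, dtype=bool)
            sel[order[:m]] = True
        else:
            rng = np.random.default_rng(seed)
            sel = np.zeros(n, dtype=bool)
            sel[rng.choice(n, size=m, replace=False)] = True
    col = out.values[feature_code].to_numpy(dtype=float)
    obs = np.isfinite(col)
    sd = np.nanstd(col, ddof=1) if obs.sum() >= 2 else 0.0
    col = np.where(sel & obs, col + shift_sd * sd, col)
    out.values[feature_code] = col
    out.meta["variant_flag"] = sel
    if table.has_coordinates() and sel.any():
        lon = out.meta["longitude"].to_numpy(dtype=float)
        lat = out.meta["latitude"].to_numpy(dtype=float)
        out.attrs["variant_region_box"] = (
            float(lon[sel].min()),
            float(lon[sel].max()),
            float(lat[sel].min()),
            float(lat[sel].max()),
        )
    return out


def generate_divergence_table(
    n_pairs: int = 9,
    correlation_mode: str = "independent",
    seed: int = 0,
    delta_p_range: tuple[float, float] = (70.0, 190.0),
    time_range: tuple[float, float] = (0.005, 0.021),
) -> pd.DataFrame:
    """Per-pair divergence scores with relative mtDNA divergence times.

    ``monotone`` mode sorts the times to match the rank order of the
    scores (rank correlation 1); ``independent`` draws them separately.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if correlation_mode not in ("independent", "monotone"):
        raise ValueError("correlation_mode must be 'independent' or 'monotone'")
    rng = np.random.default_rng(seed)
    dp = rng.uniform(*delta_p_range, size=n_pairs)
    times = rng.uniform(*time_range, size=n_pairs)
    if correlation_mode == "monotone":
        times = np.sort(times)[np.argsort(np.argsort(dp))]
    return pd.DataFrame(
        {
            "pair_id": [f"pair{i + 1}" for i in range(n_pairs)],
            "delta_p": dp,
            "mtdna_relative_time": times,
        }
    )
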