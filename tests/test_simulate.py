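"""Synthetic song-feature generator: determinism, schema, structure."""

import numpy as np
import pytest

from songdiv import (
    FeatureTable,
    PairSimConfig,
    cluster_region_concordance,
    generate_divergence_table,
    generate_pair,
    generate_taxon,
    gower_matrix,
    inject_local_variant,
    select_k,
    spearman_correlation,
    two_sample_t,
    validate_feature_table,
)


def test_same_seed_identical_tables_cell_for_cell():
    e1, w1 = generate_pair(PairSimConfig(seed=9))
    e2, w2 = generate_pair(PairSimConfig(seed=9))
    assert e1.values.equals(e2.values) and w1.values.equals(w2.values)
    assert e1.meta.equals(e2.meta)
    e3, _ = generate_pair(PairSimConfig(seed=10))
    assert not e1.values.equals(e3.values)


def test_generated_tables_validate_and_share_schema():
    cfg = PairSimConfig(seed=4)
    east, west = generate_pair(cfg)
    assert east.codes == west.codes
    assert len(east.codes) == 20
    assert east.n_individuals == cfg.n_east and west.n_individuals == cfg.n_west
    for t in (east, west):
        report = validate_feature_table(t)
        assert report.ok, report.problems
        assert t.has_coordinates()


def test_block_missingness_is_structurally_consistent():
    cfg = PairSimConfig(seed=11, syllable_presence={"a": 1.0, "b": 1.0, "c": 0.7, "d": 0.5})
    east, _ = generate_pair(cfg)
    c_codes = [c for c in east.codes if c.endswith("c")]
    miss = east.missing_mask[c_codes]
    # a missing syllable blanks all its codes at once
    assert ((miss.sum(axis=1) == 0) | (miss.sum(axis=1) == len(c_codes))).all()
    # the syllable count tracks realised presence
    present_c = ~miss.iloc[:, 0]
    present_d = ~east.missing_mask[[c for c in east.codes if c.endswith("d")]].iloc[:, 0]
    expected = 2 + present_c.astype(int) + present_d.astype(int)
    np.testing.assert_array_equal(east.values["7"].to_numpy(), expected.to_numpy())


def test_feature_substreams_stable_under_added_features():
    base = PairSimConfig(seed=6, syllables=("a", "b"), syllable_presence={"a": 1.0, "b": 1.0})
    wider = PairSimConfig(seed=6, syllables=("a", "b", "c"),
                          syllable_presence={"a": 1.0, "b": 1.0, "c": 1.0})
    e_small, _ = generate_pair(base)
    e_wide, _ = generate_pair(wider)
    for code in ("1", "1a", "2a", "4b"):
        np.testing.assert_allclose(
            e_small.values[code].to_numpy(dtype=float),
            e_wide.values[code].to_numpy(dtype=float),
        )


def test_requested_effect_realised_in_expectation():
    cfg = PairSimConfig(seed=13, n_east=400, n_west=400, effect_sd=1.0)
    east, west = generate_pair(cfg)
    code = cfg.default_affected()[0]
    a = east.values[code].dropna()
    b = west.values[code].dropna()
    shift_sds = (b.mean() - a.mean()) / a.std()
    assert shift_sds == pytest.approx(1.0, abs=0.25)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        generate_taxon(
            PairSimConfig(
                syllables=(), include_song_duration=False, include_syllable_count=False,
                include_slur=False, include_repeat_count=False,
            ),
            "east",
        )
    with pytest.raises(ValueError):
        generate_taxon(PairSimConfig(n_east=1), "east")


def test_zero_shift_injection_changes_only_flags():
    table = generate_taxon(PairSimConfig(seed=2), "east")
    out = inject_local_variant(table, "4b", 0.0, fraction=0.25)
    assert out.values.equals(table.values)
    assert out.meta["variant_flag"].sum() == round(0.25 * table.n_individuals)
    assert "variant_region_box" in out.attrs


def test_injection_is_geographically_localized():
    table = generate_taxon(PairSimConfig(seed=2), "east")
    out = inject_local_variant(table, "4b", 2.0, fraction=0.25)
    flagged = out.meta.loc[out.meta["variant_flag"], "longitude"]
    rest = out.meta.loc[~out.meta["variant_flag"], "longitude"]
    assert flagged.max() <= rest.min()


def test_injection_rejects_categorical_feature():
    table = generate_taxon(PairSimConfig(seed=2), "east")
    with pytest.raises(ValueError):
        inject_local_variant(table, "8a", 2.0)


def test_injected_shift_detectable_by_t_test():
    table = generate_taxon(PairSimConfig(seed=8), "east")
    out = inject_local_variant(table, "4b", 4.0, fraction=0.25)
    x = out.values["4b"].to_numpy(dtype=float)
    flag = out.meta["variant_flag"].to_numpy()
    _, _, p = two_sample_t(x[flag & np.isfinite(x)], x[~flag & np.isfinite(x)])
    assert p < 0.001


def test_strong_pair_shift_recovers_two_clusters():
    cfg = PairSimConfig(seed=1, effect_sd=4.0)
    east, west = generate_pair(cfg)
    pooled = FeatureTable.concat([east, west])
    D = gower_matrix(pooled)
    prof = select_k(D)
    assert prof.selected_k == 2
    conc = cluster_region_concordance(
        prof.best_clustering.assignment, pooled.taxon_labels.to_numpy()
    )
    assert conc.agreement >= 0.9


def test_divergence_table_modes():
    mono = generate_divergence_table(9, "monotone", seed=5)
    rho, _ = spearman_correlation(mono["delta_p"], mono["mtdna_relative_time"])
    assert rho == 1.0
    assert mono["mtdna_relative_time"].between(0.005, 0.021).all()
    assert mono["delta_p"].between(70, 190).all()
    # independent mode: |rho| small on average over replicates
    rhos = []
    for s in range(200):
        t = generate_divergence_table(9, "independent", seed=s)
        rhos.append(spearman_correlation(t["delta_p"], t["mtdna_relative_time"])[0])
    assert abs(np.mean(rhos)) < 0.1
    # null sd of Spearman rho is 1/sqrt(n-1) ~ 0.35 at n=9
    assert 0.2 < np.std(rhos) < 0.5


def test_divergence_table_contracts():
    with pytest.raises(ValueError):
        generate_divergence_table(2)
    with pytest.raises(ValueError):
        generate_divergence_table(5, "bogus")


def test_divergence_table_csv_round_trip(tmp_path):
    from songdiv import read_divergence_table

    table = generate_divergence_table(9, "independent", seed=3)
    path = tmp_path / "div.csv"
    table.to_csv(path, index=False)
    back = read_divergence_table(path)
    np.testing.assert_allclose(back["delta_p"], table["delta_p"])
    bad = tmp_path / "bad.csv"
    table.assign(delta_p=-1.0).to_csv(bad, index=False)
    with pytest.raises(Exception, match="non-negative"):
        read_divergence_table(bad)
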