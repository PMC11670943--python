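"""Permutation test, p-value adjustment, Delta-p, effect sizes, Spearman."""

import numpy as np
import pytest
from scipy import stats

from songdiv import (
    adjust_pvalues,
    bonferroni_threshold,
    categorize_dissimilarities,
    delta_p,
    hedges_g,
    joint_ecdf_percentile,
    permutation_test,
    spearman_correlation,
    two_sample_t,
)
from songdiv.divergence import DivergenceError
from conftest import make_table


def random_symmetric(rng, n):
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    return D


# -- categorization -----------------------------------------------------


def test_category_sizes_are_combinatorial(rng):
    D = random_symmetric(rng, 5)
    labels = ["east"] * 3 + ["west"] * 2
    cat = categorize_dissimilarities(D, labels)
    assert cat.counts() == {"within_east": 3, "within_west": 1, "between": 6}
    n = 5
    assert sum(cat.counts().values()) == n * (n - 1) // 2
    # disjoint, exhaustive partition of the strict upper triangle
    all_pairs = set(cat.pairs_within_east) | set(cat.pairs_within_west) | set(
        cat.pairs_between
    )
    assert len(all_pairs) == n * (n - 1) // 2


def test_single_taxon_rejected(rng):
    with pytest.raises(DivergenceError):
        categorize_dissimilarities(random_symmetric(rng, 4), ["east"] * 4)


# -- permutation test ---------------------------------------------------


def test_constant_matrix_gives_null_statistic_and_p_one():
    D = np.full((8, 8), 0.3)
    np.fill_diagonal(D, 0)
    labels = ["east"] * 4 + ["west"] * 4
    res = permutation_test(D, labels, "between_vs_within_east", B=199, seed=1)
    assert res.observed_stat == pytest.approx(0.0)
    assert res.p_raw == 1.0


def test_strong_shift_reaches_p_floor(rng):
    # between-dissimilarities far exceed within: only a permutation that
    # recreates the original partition can tie the observed statistic, and
    # with C(24,12) ~ 2.7M arrangements none of the B draws does
    n = 24
    labels = np.array(["east"] * 12 + ["west"] * 12)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = 0.9 if labels[i] != labels[j] else 0.05
    B = 499
    res = permutation_test(D, labels, "between_vs_within_east", B=B, seed=3)
    assert res.p_raw == pytest.approx(1 / (B + 1))


def test_permutation_reproducible_given_seed(rng):
    D = random_symmetric(rng, 12)
    labels = ["east"] * 6 + ["west"] * 6
    r1 = permutation_test(D, labels, "within_vs_within", B=299, seed=42)
    r2 = permutation_test(D, labels, "within_vs_within", B=299, seed=42)
    assert r1.p_raw == r2.p_raw and r1.observed_stat == r2.observed_stat


def test_permutation_p_super_uniform_under_null(rng):
    # exchangeable null: p-values should be (super-)uniform
    pvals = []
    for _ in range(300):
        D = random_symmetric(rng, 12)
        labels = ["east"] * 6 + ["west"] * 6
        pvals.append(
            permutation_test(D, labels, "between_vs_within_east", B=99,
                             seed=int(rng.integers(2**31))).p_raw
        )
    # rejection rate at several alphas never exceeds alpha by much
    for alpha in (0.05, 0.1, 0.2):
        rate = np.mean([p <= alpha for p in pvals])
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 300)


def test_permutation_input_contracts(rng):
    D = random_symmetric(rng, 6)
    labels = ["east"] * 3 + ["west"] * 3
    with pytest.raises(DivergenceError):
        permutation_test(D, labels, "nonsense", B=199)
    with pytest.raises(DivergenceError):
        permutation_test(D, labels, "within_vs_within", B=50)
    with pytest.raises(DivergenceError):
        permutation_test(D, ["east"] * 5 + ["west"], "within_vs_within", B=199)


# -- p adjustment -------------------------------------------------------


def test_bonferroni_printed_criterion():
    assert f"{bonferroni_threshold(0.05, 27):.3g}" == "0.00185"


def test_single_p_unchanged():
    assert adjust_pvalues([0.03], "bonferroni") == [0.03]
    assert adjust_pvalues([0.03], "benjamini_hochberg") == [0.03]


def test_bh_step_up_hand_example():
    adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_adjusted_at_least_raw_and_monotone(rng):
    p = sorted(rng.random(10).tolist())
    for method in ("benjamini_hochberg", "bonferroni"):
        adj = adjust_pvalues(p, method)
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))
    bh = adjust_pvalues(p, "benjamini_hochberg")
    assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bh, bh[1:]))


def test_family_size_extends_the_correction():
    assert adjust_pvalues([0.01], "bonferroni", family_size=27) == [0.27]
    with pytest.raises(DivergenceError):
        adjust_pvalues([], "bonferroni")


# -- joint ECDF & Delta-p ----------------------------------------------


def test_ecdf_percentiles():
    pool = [1, 2, 3, 4, 5, 6]
    assert joint_ecdf_percentile(pool, 2) == pytest.approx(100 * 2 / 6)
    assert joint_ecdf_percentile(pool, 0.5) == 0.0
    assert joint_ecdf_percentile(pool, 6) == 100.0
    with pytest.raises(DivergenceError):
        joint_ecdf_percentile([], 1.0)


def test_delta_p_worked_example():
    east = make_table({"1": [1.0, 2.0, 3.0]})
    west = make_table({"1": [4.0, 5.0, 6.0]}, taxa=["west"] * 3)
    res = delta_p(east, west)
    np.testing.assert_allclose(
        res.coordinates.loc["1"], [100 * 2 / 6, 100 * 5 / 6], atol=1e-12
    )
    assert res.delta_p == pytest.approx(50.0, abs=1e-12)


def test_delta_p_zero_for_identical_populations():
    t = make_table({"1": [1.0, 2.0, 3.0], "2": [5.0, 6.0, 7.0]})
    assert delta_p(t, t).delta_p == 0.0


def test_delta_p_invariant_under_monotone_transform(rng):
    a = rng.random(10) + 0.5
    b = rng.random(12) + 1.0
    east = make_table({"1": a})
    west = make_table({"1": b}, taxa=["west"] * 12)
    east_log = make_table({"1": np.log(a)})
    west_log = make_table({"1": np.log(b)}, taxa=["west"] * 12)
    assert delta_p(east, west).delta_p == pytest.approx(
        delta_p(east_log, west_log).delta_p, abs=1e-12
    )


def test_delta_p_symmetry_and_bound(rng):
    east = make_table({c: rng.random(8) for c in ["1", "2", "3"]})
    west = make_table(
        {c: rng.random(9) * 2 for c in ["1", "2", "3"]}, taxa=["west"] * 9
    )
    r1, r2 = delta_p(east, west), delta_p(west, east)
    assert r1.delta_p == pytest.approx(r2.delta_p)
    assert 0 <= r1.delta_p <= 100 * np.sqrt(len(r1.features_used))


def test_delta_p_drops_unshared_features_and_errors_when_none():
    east = make_table({"1": [1.0, 2.0], "2": [None, None]})
    west = make_table({"1": [3.0, 4.0], "2": [5.0, 6.0]}, taxa=["west"] * 2)
    res = delta_p(east, west)
    assert res.features_used == ["1"] and res.features_dropped == ["2"]
    east_empty = make_table({"2": [None, None]})
    west_b = make_table({"2": [5.0, 6.0]}, taxa=["west"] * 2)
    with pytest.raises(DivergenceError):
        delta_p(east_empty, west_b)


def test_delta_p_missing_cells_perturb_less_than_feature_removal(rng):
    cols = {c: rng.random(30) + i for i, c in enumerate(["1", "2", "3", "4", "1a"])}
    east = make_table(cols)
    west = make_table(
        {c: v + 0.5 for c, v in cols.items()}, taxa=["west"] * 30
    )
    base = delta_p(east, west).delta_p
    # delete 20% of cells at random
    holey = east.copy()
    for c in holey.codes:
        col = holey.values[c].copy()
        col[rng.random(30) < 0.2] = np.nan
        holey.values[c] = col
    perturbed = abs(delta_p(holey, west).delta_p - base)
    dropped = abs(
        delta_p(east.subset_features(["1", "2", "3"]), west).delta_p - base
    )
    assert perturbed < dropped


# -- effect sizes and t-test -------------------------------------------


def test_hedges_g_hand_example_and_antisymmetry():
    a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
    assert hedges_g(a, b) == pytest.approx(-1.6, abs=1e-12)
    assert hedges_g(b, a) == pytest.approx(1.6, abs=1e-12)
    assert hedges_g(a, a) == 0.0
    with pytest.raises(DivergenceError):
        hedges_g([1.0, 1.0], [1.0, 1.0])


def test_two_sample_t_hand_example():
    t, df, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "pooled")
    assert t == pytest.approx(-3.674, abs=5e-4)
    assert df == 4
    # identical samples
    t0, _, p0 = two_sample_t([1.0, 2.0], [1.0, 2.0])
    assert t0 == 0 and p0 == 1.0


def test_pooled_df_formula(rng):
    a, b = rng.random(12), rng.random(13)
    _, df, _ = two_sample_t(a, b, "pooled")
    assert df == 23
    _, df_w, _ = two_sample_t(a, b * 10, "welch")
    assert df_w < 23  # Satterthwaite reduces df under unequal variance


# -- Spearman -----------------------------------------------------------


def test_spearman_perfect_and_reversed():
    x = np.arange(1, 10, dtype=float)
    rho, p = spearman_correlation(x, x**2)
    assert rho == 1.0
    rho_r, _ = spearman_correlation(x, -x)
    assert rho_r == -1.0


def test_spearman_matches_rank_formula_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        rho, _ = spearman_correlation(x, y)
        d2 = np.sum((stats.rankdata(x) - stats.rankdata(y)) ** 2)
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)


def test_spearman_exact_p_agrees_with_large_sample_direction(rng):
    x = np.array([1.0, 2, 3, 4, 5, 6, 7])
    y = np.array([2.0, 1, 4, 3, 6, 5, 7])
    rho, p_exact = spearman_correlation(x, y)
    assert 0 < p_exact < 0.1  # strongly concordant rankings
    with pytest.raises(DivergenceError):
        spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
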