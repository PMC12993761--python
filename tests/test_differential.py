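"""Binomial GLM + LRT, Gaussian average test, BH adjustment, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from editome import (
    adjust_pvalues,
    average_glm,
    pca_on_sites,
    select_differential,
    site_glm_lrt,
)
from editome.differential import binomial_lrt_matrix
from helpers_oracles import oracle_pca_fractions

GROUPS_7V7 = ["sepsis"] * 7 + ["control"] * 7


def test_identical_groups_give_null_fit():
    ref = [40, 41, 39, 40, 40, 41, 39] * 2
    alt = [10, 9, 11, 10, 10, 9, 11] * 2
    res = site_glm_lrt(ref, alt, GROUPS_7V7)
    assert res["lrt_stat"] == pytest.approx(0.0, abs=1e-9)
    assert res["p_value"] == pytest.approx(1.0, abs=1e-6)
    assert res["beta_group"] == pytest.approx(0.0, abs=1e-9)


def test_all_zero_alt_is_p_one_by_convention():
    res = site_glm_lrt([50] * 14, [0] * 14, GROUPS_7V7)
    assert res["p_value"] == 1.0
    assert res["lrt_stat"] == 0.0
    assert res["degenerate"]


def test_missing_group_is_untestable():
    res = site_glm_lrt([50] * 7 + [0] * 7, [5] * 7 + [0] * 7, GROUPS_7V7)
    assert not res["testable"]
    assert np.isnan(res["p_value"])


def test_lrt_matches_statsmodels_glm():
    """Closed-form fit agrees with an iteratively fitted binomial GLM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    for _ in range(10):
        depth = rng.integers(20, 80, size=14)
        p = np.where(np.arange(14) < 7, 0.3, 0.18)
        alt = rng.binomial(depth, p)
        res = site_glm_lrt(depth - alt, alt, GROUPS_7V7)
        X = sm.add_constant((np.arange(14) < 7).astype(float))
        y = np.column_stack([alt, depth - alt])
        fit1 = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fit0 = sm.GLM(y, np.ones((14, 1)), family=sm.families.Binomial()).fit()
        lrt_sm = 2 * (fit1.llf - fit0.llf)
        assert res["lrt_stat"] == pytest.approx(lrt_sm, abs=1e-6)
        assert res["beta_group"] == pytest.approx(fit1.params[1], abs=1e-6)


def test_loglik_matches_brute_force_grid():
    """The fitted deviance difference equals a brute-force maximization of
    the binomial likelihood over group probabilities."""
    from scipy.special import xlogy

    rng = np.random.default_rng(9)
    depth = rng.integers(30, 70, size=14)
    alt = rng.binomial(depth, np.where(np.arange(14) < 7, 0.35, 0.2))
    case = np.arange(14) < 7

    def ll(p_case, p_ctrl):
        p = np.where(case, p_case, p_ctrl)
        return float((xlogy(alt, p) + xlogy(depth - alt, 1 - p)).sum())

    grid = np.linspace(1e-4, 1 - 1e-4, 4001)
    # the two group probabilities separate in the likelihood, so profile each
    best_case = grid[np.argmax([ll(g, 0.5) - ll(0.5, 0.5) for g in grid])]
    best_ctrl = grid[np.argmax([ll(0.5, g) - ll(0.5, 0.5) for g in grid])]
    ll_alt = ll(best_case, best_ctrl)
    ll_null = max(ll(g, g) for g in grid)
    lrt_grid = 2 * (ll_alt - ll_null)
    res = site_glm_lrt(depth - alt, alt, GROUPS_7V7)
    assert res["lrt_stat"] == pytest.approx(lrt_grid, abs=1e-5)


def test_label_swap_negates_beta_keeps_p():
    rng = np.random.default_rng(2)
    depth = rng.integers(30, 70, size=(20, 14))
    alt = rng.binomial(depth, 0.25)
    case = np.arange(14) < 7
    a = binomial_lrt_matrix(alt, depth, case)
    b = binomial_lrt_matrix(alt, depth, ~case)
    np.testing.assert_allclose(a["beta_group"], -b["beta_group"], atol=1e-10)
    np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)


def test_quasibinomial_is_more_conservative_under_overdispersion():
    rng = np.random.default_rng(8)
    depth = rng.integers(40, 60, size=(200, 14))
    # logit-normal noise: strong overdispersion relative to binomial
    from scipy.special import expit

    p = expit(rng.normal(-1.1, 0.6, size=(200, 14)))
    alt = rng.binomial(depth, p)
    case = np.arange(14) < 7
    plain = binomial_lrt_matrix(alt, depth, case)["p_value"]
    quasi = binomial_lrt_matrix(alt, depth, case, family="quasibinomial")["p_value"]
    assert (quasi >= plain - 1e-12).mean() > 0.95
    assert (quasi < 0.05).mean() < (plain < 0.05).mean()


# -- Gaussian GLM on averages ----------------------------------------------

def test_average_glm_null_and_separated():
    # identical group means/variances, symmetric data
    _, p, lrt = average_glm([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert p == pytest.approx(1.0)
    assert lrt == pytest.approx(0.0, abs=1e-12)
    # zero within-group variance, different means -> p ~ 0
    _, p, _ = average_glm([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
    assert p < 1e-10
    # constant response
    _, p, _ = average_glm([5, 5, 5, 5], ["a", "a", "b", "b"])
    assert p == 1.0


def test_average_glm_matches_statsmodels_ols_lrt():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, size=12) + np.repeat([0.0, 0.8], 6)
    lab = ["a"] * 6 + ["b"] * 6
    eff, p, lrt = average_glm(y, lab, case_label="b")
    X = sm.add_constant((np.array(lab) == "b").astype(float))
    fit1 = sm.OLS(y, X).fit()
    fit0 = sm.OLS(y, np.ones((12, 1))).fit()
    assert lrt == pytest.approx(2 * (fit1.llf - fit0.llf), abs=1e-8)
    assert eff == pytest.approx(fit1.params[1], abs=1e-10)


# -- BH adjustment ----------------------------------------------------------

def test_bh_hand_computations():
    assert adjust_pvalues([0.04]) == pytest.approx([0.04])
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(adjust_pvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
def test_bh_monotone_and_dominates_p(ps):
    p = np.asarray(ps)
    q = adjust_pvalues(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_select_differential_sites_and_genes():
    res = pd.DataFrame(
        {"site_id": ["s1", "s2"], "gene_id": ["G", "H"],
         "p_value": [0.01, 0.2], "q_value": [0.02, 0.2]}
    )
    sites, genes = select_differential(res)
    assert sites == ["s1"] and genes == ["G"]
    sites, genes = select_differential(res.assign(p_value=[0.5, 0.9]))
    assert sites == [] and genes == []


# -- PCA --------------------------------------------------------------------

def test_pca_rank_one_and_normalization():
    lv = pd.DataFrame(
        np.outer([0.1, 0.2, 0.3], [1, 2, 1, 3]),
        index=["s1", "s2", "s3"], columns=["a", "b", "c", "d"],
    )
    res = pca_on_sites(lv)
    assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(0)
    lv = pd.DataFrame(rng.random((6, 5)))
    res = pca_on_sites(lv)
    assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(res.variance_fraction) <= 1e-12).all()


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(1)
    for _ in range(5):
        lv = pd.DataFrame(rng.random((5, 4)))  # 5 sites x 4 samples
        res = pca_on_sites(lv)
        expected = oracle_pca_fractions(lv.to_numpy().T)
        np.testing.assert_allclose(res.variance_fraction, expected[: len(res.variance_fraction)], atol=1e-9)


def test_pca_invariant_to_duplicating_samples():
    rng = np.random.default_rng(3)
    lv = pd.DataFrame(rng.random((6, 4)), columns=list("abcd"))
    dup = pd.concat([lv, lv.add_suffix("_2", axis=1)], axis=1)
    a = pca_on_sites(lv).variance_fraction
    b = pca_on_sites(dup).variance_fraction
    np.testing.assert_allclose(a, b[: len(a)], atol=1e-9)


def test_pca_imputes_missing_with_site_mean():
    lv = pd.DataFrame(
        [[0.1, 0.2, np.nan], [0.4, 0.5, 0.6]],
        index=["site1", "site2"], columns=["s1", "s2", "s3"],
    )
    filled = lv.copy()
    filled.loc["site1", "s3"] = filled.loc["site1", ["s1", "s2"]].mean()
    np.testing.assert_allclose(
        pca_on_sites(lv).variance_fraction, pca_on_sites(filled).variance_fraction
    )
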