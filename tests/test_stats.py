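"""ANOVA/Tukey, mixed-model likelihoods, AICc ranking and importance."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fallowcarbon import (aicc, all_subsets_selection, anova_tukey,
                          collinearity_screen, fit_lmm, variable_importance)
from fallowcarbon.stats import CANDIDATE_VARS, standardize


def _site_frame(seed=0, beta_ps=0.0, beta_soc=0.0, cat_sd=2.0, noise=1.0):
    """20 fallow sites (4 categories x 5) with random covariates and a
    response built from known PS/SOC effects plus a category effect."""
    rng = np.random.default_rng(seed)
    cats = np.repeat(["SA0_5", "SA6_10", "SA11_20", "SA21_30"], 5)
    df = pd.DataFrame({
        "category": cats,
        "FA": rng.uniform(1, 30, 20),
        "DIS": rng.uniform(100, 3000, 20),
        "SL": rng.uniform(5, 35, 20),
        "PS": rng.uniform(1, 20, 20),
        "SOC": rng.uniform(2, 8, 20),
    })
    cat_eff = dict(zip(np.unique(cats), rng.normal(0, cat_sd, 4)))
    z = standardize(df, ["PS", "SOC"])
    df["response"] = (
        30 + beta_ps * z["PS"] + beta_soc * z["SOC"]
        + np.array([cat_eff[c] for c in cats])
        + rng.normal(0, noise, 20)
    )
    return df


def test_two_group_anova_equals_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
    res = anova_tukey(np.r_[a, b], ["g1"] * 8 + ["g2"] * 8)
    t, p = sps.ttest_ind(a, b)
    assert res.F == pytest.approx(t ** 2, rel=1e-9)
    assert res.p == pytest.approx(p, rel=1e-9)
    assert (res.df_between, res.df_within) == (1, 14)


def test_identical_groups_give_zero_f():
    res = anova_tukey([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert not any(sig for *_, sig in res.tukey_pairs)


def test_small_group_rejected():
    with pytest.raises(ValueError):
        anova_tukey([1, 2, 3], ["a", "a", "b"])


def test_aicc_hand_values_and_limits():
    assert aicc(0.0, 2, 20) == pytest.approx(4 + 12 / 17, rel=1e-12)
    assert aicc(-10.0, 3, 10 ** 9) == pytest.approx(26.0, abs=1e-6)  # -> AIC
    with pytest.raises(ValueError):
        aicc(0.0, 5, 6)


def test_null_model_on_zero_variance_response():
    df = _site_frame()
    df["response"] = 5.0
    with pytest.warns(UserWarning):
        fit = fit_lmm(df, "response", ())
    assert fit.df == 3  # intercept + 2 variance components
    assert np.isfinite(fit.loglik)
    assert fit.params[0] == pytest.approx(5.0)


def test_adding_a_covariate_never_decreases_loglik():
    df = standardize(_site_frame(seed=3, beta_ps=5, noise=2), CANDIDATE_VARS)
    chain = [(), ("PS",), ("PS", "SOC"), ("PS", "SOC", "SL")]
    lls = [fit_lmm(df, "response", s).loglik for s in chain]
    for smaller, larger in zip(lls, lls[1:]):
        assert larger >= smaller - 1e-6


def test_known_slope_recovered_within_two_se():
    df = _site_frame(seed=7, beta_ps=2.0, cat_sd=1.0, noise=0.5)
    df_z = standardize(df, CANDIDATE_VARS)
    fit = fit_lmm(df_z, "response", ("PS",))
    assert abs(fit.params[1] - 2.0) <= 2 * fit.bse[1]


def test_selection_table_matches_brute_force_enumeration():
    """Independent enumeration over all 32 subsets with the same fitter
    reproduces the table row-for-row (AICc, delta, weights)."""
    df = _site_frame(seed=11, beta_ps=8, beta_soc=5, noise=2)
    table = all_subsets_selection(df, "response")
    assert len(table) == 32
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    assert table.iloc[0]["delta_aicc"] == 0.0

    dfz = standardize(df, CANDIDATE_VARS)
    oracle = {}
    for size in range(6):
        for subset in itertools.combinations(CANDIDATE_VARS, size):
            fit = fit_lmm(dfz, "response", subset)
            oracle[subset] = aicc(fit.loglik, fit.df, 20)
    best = min(oracle.values())
    rel = {s: np.exp(-0.5 * (a - best)) for s, a in oracle.items()}
    z = sum(rel.values())
    for _, row in table.iterrows():
        s = tuple(row["vars"])
        assert row["aicc"] == pytest.approx(oracle[s], rel=1e-9)
        assert row["delta_aicc"] == pytest.approx(oracle[s] - best, abs=1e-9)
        assert row["weight"] == pytest.approx(rel[s] / z, rel=1e-9)
    assert (table["aicc"].values == np.sort(table["aicc"].values)).all()


def test_importance_equals_filter_sum_oracle():
    df = _site_frame(seed=13, beta_ps=6, noise=2)
    table = all_subsets_selection(df, "response")
    imp = variable_importance(table).set_index("variable")
    for var in CANDIDATE_VARS:
        mask = table["vars"].apply(lambda t: var in t)
        assert imp.loc[var, "importance"] == pytest.approx(
            table.loc[mask, "weight"].sum(), abs=1e-12)
        assert imp.loc[var, "n_models"] == 16
    # equivalence-set scope only counts flagged rows
    imp_eq = variable_importance(table, scope="equivalence_set")
    eq = table.loc[table["equivalent"]]
    got = imp_eq.set_index("variable")
    for var in CANDIDATE_VARS:
        mask = eq["vars"].apply(lambda t: var in t)
        assert got.loc[var, "n_models"] == int(mask.sum())


def test_duplicate_covariates_tie_symmetrically():
    """Two identical candidate variables yield identical single-variable
    models: equal AICc and equal weights."""
    df = _site_frame(seed=17, beta_ps=4, noise=1)
    df["PS2"] = df["PS"]
    table = all_subsets_selection(df, "response", candidates=("PS", "PS2"))
    one = table[table["subset"] == "PS"].iloc[0]
    two = table[table["subset"] == "PS2"].iloc[0]
    assert one["aicc"] == pytest.approx(two["aicc"], rel=1e-9)
    assert one["weight"] == pytest.approx(two["weight"], rel=1e-6)


def test_variable_in_every_or_no_model():
    df = _site_frame(seed=19)
    table = all_subsets_selection(df, "response", candidates=("PS",))
    assert len(table) == 2
    imp = variable_importance(table, candidates=("PS", "SOC")).set_index("variable")
    assert 0 <= imp.loc["PS", "importance"] <= 1
    assert imp.loc["SOC", "importance"] == 0.0  # never a candidate -> no model
    assert imp.loc["SOC", "n_models"] == 0


def test_collinearity_screen():
    rng = np.random.default_rng(23)
    df = pd.DataFrame({
        "FA": rng.normal(size=50), "PS": rng.normal(size=50),
    })
    df["E"] = df["FA"] * 1.0          # perfect copy -> excluded
    df["flat"] = 1.0                  # constant -> excluded with warning
    with pytest.warns(UserWarning):
        retained, excluded = collinearity_screen(df, priority=("FA", "PS"))
    assert retained == ["FA", "PS"]
    assert set(excluded) == {"E", "flat"}
    # orthogonal covariates all retained
    df2 = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
    retained, excluded = collinearity_screen(df2, priority=())
    assert excluded == [] and set(retained) == {"a", "b", "c"}
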