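"""Clustered GLS, three-level mixed model, orthogonal basis and interactions."""

import numpy as np
import pandas as pd
import pytest

from grsgrowth import InputError
from grsgrowth.association import (AgeInteractionModel, ClusteredGLS,
                                   OrthoAgeBasis, ThreeLevelModel,
                                   score_distribution_summary)
from grsgrowth._nested import fit_nested_ml

from helpers import dense_nested_ml, make_nested_data


def _sim_interaction(rng, n_fam=80, kids=2, obs=6, delta0=0.0, delta1=0.008,
                     vc=(0.2, 0.3, 0.5), max_age=45.0):
    """Observation-level data from the exact association model class."""
    fam = np.repeat(np.arange(n_fam), kids)
    n_ind = n_fam * kids
    score = rng.binomial(2, 0.35, size=(n_ind, 28)).sum(axis=1).astype(float)
    u = rng.normal(0, np.sqrt(vc[0]), n_fam)
    v = rng.normal(0, np.sqrt(vc[1]), n_ind)
    rows = []
    for i in range(n_ind):
        ages = np.sort(rng.uniform(0, max_age, obs))
        e = rng.normal(0, np.sqrt(vc[2]), obs)
        s_c = score[i] - 2 * 0.35 * 28
        z = s_c * (delta0 + delta1 * ages) + u[fam[i]] + v[i] + e
        for a, zz in zip(ages, z):
            rows.append((f"F{fam[i]}", f"I{i}", score[i], a, zz))
    return pd.DataFrame(rows, columns=["mother_id", "individual_id", "score",
                                       "age", "z"])


# ---------------------------------------------------------------- GLS

def test_singleton_clusters_collapse_to_ols(rng):
    n = 120
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, 0.3]) + rng.normal(0, 0.7, n)
    res = ClusteredGLS(y, X, np.arange(n), ["intercept", "x"]).fit()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(res.params.to_numpy(), beta_ols, rtol=1e-8)
    resid = y - X @ beta_ols
    cov_ols = (resid @ resid / n) * np.linalg.inv(X.T @ X)
    np.testing.assert_allclose(res.bse.to_numpy(), np.sqrt(np.diag(cov_ols)),
                               rtol=1e-6)


def test_gls_recovers_known_effect(rng):
    reps, beta_true = 30, 0.02
    ests = []
    for _ in range(reps):
        n_clu = 300
        sizes = rng.integers(1, 5, n_clu)
        groups = np.repeat(np.arange(n_clu), sizes)
        n = len(groups)
        score = rng.binomial(2, 0.4, size=(n, 28)).sum(axis=1).astype(float)
        u = rng.normal(0, 0.5, n_clu)[groups]
        y = 0.1 + beta_true * score + u + rng.normal(0, 0.8, n)
        X = np.column_stack([np.ones(n), score])
        res = ClusteredGLS(y, X, groups, ["intercept", "score"]).fit()
        ests.append(res.params["score"])
    ests = np.asarray(ests)
    mc_se = ests.std(ddof=1) / np.sqrt(reps)
    assert abs(ests.mean() - beta_true) <= 3 * mc_se


def test_constant_score_rejected(rng):
    n = 30
    X = np.column_stack([np.ones(n), np.full(n, 2.0)])
    y = rng.normal(size=n)
    with pytest.raises(InputError, match="constant"):
        ClusteredGLS(y, X, np.arange(n), ["intercept", "score"]).fit()


def test_single_cluster_warns_and_fits(rng):
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    with pytest.warns(UserWarning, match="OLS"):
        res = ClusteredGLS(y, X, np.zeros(n), ["intercept", "x"]).fit()
    assert np.isfinite(res.params).all()


def test_wald_ci_is_plus_minus_196_se(rng):
    y, X, fam, ind = make_nested_data(rng, n_fam=20)
    res = ThreeLevelModel(y, X, fam, ind, ["intercept", "x"]).fit()
    ci = res.conf_int()
    np.testing.assert_allclose(ci["high"] - res.params, 1.96 * res.bse,
                               rtol=1e-12)


# ---------------------------------------------------------------- oracles

def test_gls_matches_dense_oracle(rng):
    n_clu = 12
    groups = np.repeat(np.arange(n_clu), 4)[:45]
    n = len(groups)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = 0.5 + 0.2 * X[:, 1] + rng.normal(0, 0.6, n_clu)[groups] \
        + rng.normal(0, 1.0, n)
    mine = fit_nested_ml(y, X, groups)
    oracle = dense_nested_ml(y, X, groups)
    np.testing.assert_allclose(mine.params, oracle["params"], rtol=1e-6)
    assert abs(mine.sigma2_fam - oracle["sigma2_fam"]) < 1e-4
    assert abs(mine.sigma2_obs - oracle["sigma2_obs"]) < 1e-4


def test_three_level_matches_dense_oracle(rng):
    y, X, fam, ind = make_nested_data(rng, n_fam=8, kids=2, obs=3)
    assert len(y) <= 50
    mine = fit_nested_ml(y, X, fam, ind)
    oracle = dense_nested_ml(y, X, fam, ind)
    np.testing.assert_allclose(mine.params, oracle["params"], rtol=1e-6)
    for a, b in ((mine.sigma2_fam, oracle["sigma2_fam"]),
                 (mine.sigma2_ind, oracle["sigma2_ind"]),
                 (mine.sigma2_obs, oracle["sigma2_obs"])):
        assert abs(a - b) < 1e-4


def test_three_level_matches_statsmodels(rng):
    """Independent cross-check against MixedLM with a nested variance component."""
    import statsmodels.formula.api as smf

    y, X, fam, ind = make_nested_data(rng, n_fam=30, kids=3, obs=4)
    mine = fit_nested_ml(y, X, fam, ind)
    df = pd.DataFrame({"y": y, "x": X[:, 1], "fam": fam, "ind": ind})
    md = smf.mixedlm("y ~ x", df, groups="fam", re_formula="1",
                     vc_formula={"ind": "0 + C(ind)"})
    sm_fit = md.fit(reml=False)
    np.testing.assert_allclose(mine.params, sm_fit.fe_params.values, atol=1e-5)
    assert mine.llf >= sm_fit.llf - 1e-6  # our optimum is at least as good
    assert abs(mine.sigma2_obs - sm_fit.scale) < 1e-3


def test_zero_variance_components_collapse(rng):
    n_fam, kids, obs = 40, 2, 4
    y, X, fam, ind = make_nested_data(rng, n_fam=n_fam, kids=kids, obs=obs,
                                      vc=(0.8, 0.0, 0.0))
    res = ThreeLevelModel(y, X, fam, ind, ["intercept", "x"]).fit()
    assert res.variance_components["family"] < 0.05
    assert res.variance_components["individual"] < 0.05
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(res.params.to_numpy(), beta_ols, atol=0.02)


def test_non_nested_individuals_rejected(rng):
    y = rng.normal(size=6)
    X = np.ones((6, 1))
    fam = [0, 0, 0, 1, 1, 1]
    ind = [0, 0, 1, 1, 2, 2]  # individual 1 appears in both families
    with pytest.raises(InputError, match="nested"):
        fit_nested_ml(y, X, fam, ind)


def test_three_level_variance_recovery(rng):
    """Components (0.2, 0.3, 0.5) recovered at 300 families x 3 x 8."""
    y, X, fam, ind = make_nested_data(rng, n_fam=300, kids=3, obs=8,
                                      vc=(0.5, 0.3, 0.2))
    res = ThreeLevelModel(y, X, fam, ind, ["intercept", "x"]).fit()
    vc = res.variance_components
    # asymptotic SEs at this size are ~0.02; allow generous 4x margins
    assert abs(vc["family"] - 0.2) < 0.08
    assert abs(vc["individual"] - 0.3) < 0.08
    assert abs(vc["observation"] - 0.5) < 0.08


# ---------------------------------------------------------------- basis

def test_basis_symmetric_three_point_gram_schmidt():
    basis = OrthoAgeBasis.build(np.array([-1.0, 0.0, 1.0]), degree=2)
    B = basis.transform(np.array([-1.0, 0.0, 1.0]))
    lin = B[:, 0]
    np.testing.assert_allclose(lin / lin[-1], [-1.0, 0.0, 1.0], atol=1e-12)
    quad = B[:, 1]
    target = np.array([1.0, 0.0, 1.0]) - 2.0 / 3.0  # age^2 - 2/3
    np.testing.assert_allclose(quad / quad[-1], target / target[-1],
                               atol=1e-12)


def test_basis_columns_orthogonal(rng):
    ages = rng.uniform(0, 50, 300)
    basis = OrthoAgeBasis.build(ages)
    B = basis.transform(ages)
    gram = B.T @ B
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
    assert np.abs(B.sum(axis=0)).max() < 1e-8  # orthogonal to the constant


def test_basis_spans_raw_cubic(rng):
    ages = rng.uniform(0, 30, 200)
    y = ages ** 3
    basis = OrthoAgeBasis.build(ages)
    B = np.column_stack([np.ones(len(ages)), basis.transform(ages)])
    fit_b = B @ np.linalg.lstsq(B, y, rcond=None)[0]
    A = np.vander(ages, 4, increasing=True)
    fit_a = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    np.testing.assert_allclose(fit_b, fit_a, rtol=1e-8, atol=1e-8)


def test_basis_raw_coefficient_round_trip(rng):
    ages = rng.uniform(0, 50, 500)
    basis = OrthoAgeBasis.build(ages)
    gamma = rng.normal(size=3)
    raw = basis.raw_coefficients(gamma)
    t = rng.uniform(0, 50, 20)
    direct = basis.transform(t) @ gamma
    poly = raw[0] * t + raw[1] * t ** 2 + raw[2] * t ** 3
    # they differ by the constant absorbed into the intercept
    diff = direct - poly
    np.testing.assert_allclose(diff, diff[0] * np.ones_like(diff), atol=1e-8)


def test_basis_requires_enough_distinct_ages():
    with pytest.raises(InputError):
        OrthoAgeBasis.build(np.array([1.0, 1.0, 2.0, 2.0]), degree=3)


def test_basis_from_other_sample_rejected(rng):
    df = _sim_interaction(rng, n_fam=20, obs=4)
    other = OrthoAgeBasis.build(rng.uniform(0, 45, len(df)))
    with pytest.raises(InputError, match="different sample"):
        AgeInteractionModel(df["z"], df["score"], df["age"], df["mother_id"],
                            df["individual_id"], basis=other)


# ---------------------------------------------------------------- interaction

def test_interaction_null_when_effect_constant(rng):
    df = _sim_interaction(rng, n_fam=150, obs=8, delta0=0.02, delta1=0.0)
    res = AgeInteractionModel.from_dataframe(df).fit()
    slope = res.linear_slope_raw()
    assert abs(slope.coefficient) <= 3 * slope.se
    # the score main effect should pick up delta0
    assert abs(res.params["score"] - 0.02) <= 3 * res.bse["score"]


def test_interaction_recovers_linear_trajectory(rng):
    reps = 12
    ests = []
    for _ in range(reps):
        df = _sim_interaction(rng, n_fam=100, obs=6, delta1=0.008)
        res = AgeInteractionModel.from_dataframe(df).fit()
        ests.append(res.linear_slope_raw().coefficient)
    ests = np.asarray(ests)
    mc_se = ests.std(ddof=1) / np.sqrt(reps)
    assert abs(ests.mean() - 0.008) <= 3 * mc_se


def test_quadratic_trajectory_detected(rng):
    n_fam, kids, obs = 150, 2, 8
    fam = np.repeat(np.arange(n_fam), kids)
    n_ind = n_fam * kids
    score = rng.binomial(2, 0.35, size=(n_ind, 28)).sum(axis=1).astype(float)
    rows = []
    for i in range(n_ind):
        ages = np.sort(rng.uniform(0, 45, obs))
        s_c = score[i] - 2 * 0.35 * 28
        z = s_c * (0.0004 * ages ** 2) + rng.normal(0, np.sqrt(0.5), obs) \
            + rng.normal(0, np.sqrt(0.3))
        rows.extend((f"F{fam[i]}", f"I{i}", score[i], a, zz)
                    for a, zz in zip(ages, z))
    df = pd.DataFrame(rows, columns=["mother_id", "individual_id", "score",
                                     "age", "z"])
    res = AgeInteractionModel.from_dataframe(df).fit()
    assert res.wald_higher_order()["pvalue"] < 0.05


def test_mean_effect_over_sample_equals_score_main_effect(rng):
    df = _sim_interaction(rng, n_fam=60, obs=5)
    res = AgeInteractionModel.from_dataframe(df).fit()
    curve = res.predict_effect_by_age(df["age"].to_numpy())
    np.testing.assert_allclose(curve["effect"].mean(), res.params["score"],
                               rtol=1e-8)


def test_ci_band_wider_at_edges(rng):
    df = _sim_interaction(rng, n_fam=80, obs=6)
    res = AgeInteractionModel.from_dataframe(df).fit()
    lo, mid, hi = 0.0, float(df["age"].mean()), float(df["age"].max())
    curve = res.predict_effect_by_age(np.array([lo, mid, hi]))
    width = curve["ci_high"] - curve["ci_low"]
    assert width.iloc[0] >= width.iloc[1]
    assert width.iloc[2] >= width.iloc[1]


def test_linear_truth_gives_straight_line(rng):
    df = _sim_interaction(rng, n_fam=200, obs=8, delta1=0.01)
    res = AgeInteractionModel.from_dataframe(df).fit()
    assert res.wald_higher_order()["pvalue"] > 0.001  # no spurious curvature
    raw = res.raw_interaction_coefficients()
    # quadratic/cubic raw-age coefficients are consistent with zero
    assert abs(raw[0] - 0.01) < 0.01


def test_extrapolation_flagged_in_effect_curve(rng):
    df = _sim_interaction(rng, n_fam=30, obs=5, max_age=30.0)
    res = AgeInteractionModel.from_dataframe(df).fit()
    curve = res.predict_effect_by_age(np.array([5.0, 100.0]))
    assert not curve["extrapolated"].iloc[0]
    assert curve["extrapolated"].iloc[1]


def test_summary_renders(rng):
    df = _sim_interaction(rng, n_fam=20, obs=4)
    res = AgeInteractionModel.from_dataframe(df).fit()
    text = res.summary()
    assert "score:age1" in text and "Variance components" in text


# ---------------------------------------------------------------- figure 1

def test_score_summary_constant_outcome():
    out = score_distribution_summary([1, 1, 2, 2], [0.5, 0.5, 0.5, 0.5])
    assert (out["mean_z"] == 0.5).all()
    assert np.allclose(out["se_z"], 0.0)


def test_score_summary_singleton_bin():
    out = score_distribution_summary([1, 2, 2], [0.1, 0.2, 0.3])
    assert np.isnan(out.loc[out["score_bin"] == 1, "se_z"]).all()


def test_score_summary_positive_effect_slopes_up(rng):
    score = rng.binomial(2, 0.4, size=(3000, 28)).sum(axis=1).astype(float)
    z = 0.05 * score + rng.normal(0, 1, 3000)
    out = score_distribution_summary(score, z)
    big = out.loc[out["n"] >= 20]
    slope = np.polyfit(big["score_bin"], big["mean_z"], 1)[0]
    assert slope > 0
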