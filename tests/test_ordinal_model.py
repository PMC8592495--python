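"""Weighted proportional-odds fitting, pooling, prediction and the LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from frailmap.frailty_index import DeficitSchema, score_table
from frailmap.ordinal_model import (
    OrdinalFit,
    fit_proportional_odds,
    lrt_interaction,
    pool_rubin,
    predict_strata,
)
from frailmap.strata import AGE_BANDS


def _table(age, sex, quintile, category, weight=None):
    df = pd.DataFrame(
        {
            "age_band": age,
            "sex": sex,
            "imd_quintile": quintile,
            "frailty_category": category,
        }
    )
    if weight is not None:
        df["weight"] = weight
    return df


def _scored_survey(truth_pair):
    survey, _ = truth_pair
    return score_table(survey, DeficitSchema.default(30))


@pytest.fixture(scope="module")
def scored(complete_survey):
    return _scored_survey(complete_survey)


def test_null_model_recovers_weighted_cumulative_shares():
    """With no predictor variation, expit(theta_1) equals the weighted
    share robust and expit(theta_2) the weighted share robust+pre-frail."""
    rng = np.random.default_rng(0)
    n = 300
    cats = rng.choice(["robust", "pre_frail", "frail"], size=n, p=[0.5, 0.3, 0.2])
    w = rng.uniform(0.5, 2.0, size=n)
    t = _table(["50-54"] * n, ["male"] * n, [1] * n, cats, w)
    fit = fit_proportional_odds(t)
    share1 = w[cats == "robust"].sum() / w.sum()
    share2 = w[cats != "frail"].sum() / w.sum()
    assert expit(fit.params["theta_1"]) == pytest.approx(share1, abs=1e-8)
    assert expit(fit.params["theta_2"]) == pytest.approx(share2, abs=1e-8)
    assert fit.params["theta_1"] < fit.params["theta_2"]
    assert fit.loglik <= 0


def test_weight_rescaling_leaves_estimates_unchanged(scored):
    sub = scored.iloc[:800]
    f1 = fit_proportional_odds(sub)
    doubled = sub.copy()
    doubled["weight"] = doubled["weight"] * 2.0
    f2 = fit_proportional_odds(doubled)
    pd.testing.assert_series_equal(f1.params, f2.params, atol=1e-7, rtol=0)
    assert f2.sum_weights == pytest.approx(2 * f1.sum_weights)


def test_unit_weights_equal_unweighted(scored):
    sub = scored.iloc[:600].copy()
    sub["weight"] = 1.0
    f_w = fit_proportional_odds(sub)
    f_u = fit_proportional_odds(sub.drop(columns="weight"))
    pd.testing.assert_series_equal(f_w.params, f_u.params, atol=1e-10, rtol=0)


def test_fit_matches_statsmodels_ordered_model(scored):
    """Unweighted cross-check against an independent implementation."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    sub = scored.iloc[:1500].copy()
    sub["weight"] = 1.0
    ours = fit_proportional_odds(sub)

    endog = pd.Series(
        pd.Categorical(
            sub["frailty_category"].astype(str),
            categories=["robust", "pre_frail", "frail"],
            ordered=True,
        )
    )
    exog = pd.get_dummies(
        sub[["age_band", "sex", "imd_quintile"]].astype(str), drop_first=False
    )
    keep = [f"age_band_{b}" for b in AGE_BANDS[1:] if f"age_band_{b}" in exog] + [
        "sex_female"
    ] + [f"imd_quintile_{q}" for q in (2, 3, 4, 5) if f"imd_quintile_{q}" in exog]
    exog = exog[keep].astype(float)
    sm_fit = OrderedModel(endog, exog, distr="logit").fit(
        method="bfgs", disp=False, gtol=1e-10
    )
    # compare via log-likelihood and coefficients
    assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
    sm_beta = sm_fit.params[: exog.shape[1]].to_numpy()
    np.testing.assert_allclose(ours.beta.to_numpy(), sm_beta, atol=2e-4)


def test_absent_category_raises():
    t = _table(["50-54"] * 10, ["male"] * 10, [1] * 10, ["robust"] * 5 + ["frail"] * 5)
    with pytest.raises(ValueError, match="pre_frail"):
        fit_proportional_odds(t)


def test_covariance_is_symmetric_positive_and_sandwich_available(scored):
    sub = scored.iloc[:1000]
    f = fit_proportional_odds(sub)
    cov = f.cov.to_numpy()
    assert np.allclose(cov, cov.T)
    assert (np.diag(cov) > 0).all()
    f_sw = fit_proportional_odds(sub, cov_type="sandwich")
    pd.testing.assert_series_equal(f.params, f_sw.params)
    assert not np.allclose(f_sw.cov.to_numpy(), cov)


def _fake_fit(values, variances):
    names = [f"p{i}" for i in range(len(values))]
    return OrdinalFit(
        params=pd.Series(values, index=names),
        cov=pd.DataFrame(np.diag(variances), index=names, columns=names),
        loglik=-1.0, n=10, sum_weights=10.0, n_iter=1, converged=True,
    )


def test_rubin_pooling_rules():
    # m identical fits: point unchanged, between-variance zero
    f = _fake_fit([1.0, 2.0], [0.1, 0.2])
    pooled = pool_rubin([f, f, f])
    assert pooled.params.tolist() == [1.0, 2.0]
    assert np.allclose(pooled.between.to_numpy(), 0.0)
    assert np.allclose(pooled.cov.to_numpy(), pooled.within.to_numpy())

    # m = 1: totals equal the single fit
    pooled1 = pool_rubin([f])
    assert np.allclose(pooled1.cov.to_numpy(), f.cov.to_numpy())

    # hand computation: estimates 1.0 and 2.0, variances 0.5 each
    # -> point 1.5, B = 0.5, T = 0.5 + 1.5 * 0.5 = 1.25
    fa, fb = _fake_fit([1.0], [0.5]), _fake_fit([2.0], [0.5])
    pooled2 = pool_rubin([fa, fb])
    assert pooled2.params.iloc[0] == pytest.approx(1.5)
    assert pooled2.cov.iloc[0, 0] == pytest.approx(1.25)

    with pytest.raises(ValueError, match="mismatched"):
        pool_rubin([fa, _fake_fit([1.0, 2.0], [0.5, 0.5])])


def test_predict_strata_identities(scored):
    fit = fit_proportional_odds(scored)
    pred = predict_strata(fit)
    assert len(pred) == 90
    total = pred[["p_robust", "p_prefrail", "p_frail"]].sum(axis=1)
    assert np.allclose(total, 1.0, atol=1e-12)
    ref = pred[
        (pred["age_band"] == "50-54")
        & (pred["sex"] == "male")
        & (pred["imd_quintile"] == 1)
    ].iloc[0]
    assert ref["p_robust"] == pytest.approx(expit(fit.params["theta_1"]), abs=1e-12)

    # proportional-odds monotonicity: sort by eta and check p_robust ordering
    beta = fit.beta
    eta = np.zeros(len(pred))
    for name, b in beta.items():
        if name.startswith("age_"):
            eta += (pred["age_band"] == name[4:]).to_numpy() * b
        elif name == "sex_female":
            eta += (pred["sex"] == "female").to_numpy() * b
        else:
            eta += (pred["imd_quintile"] == int(name[4:])).to_numpy() * b
    order = np.argsort(eta)
    assert (np.diff(pred["p_robust"].to_numpy()[order]) <= 1e-12).all()


def _simulate_po(rng, n, beta_sex, beta_age, interaction):
    """Simulate categories from a proportional-odds model with a possible
    age x sex interaction (two age groups only, for speed)."""
    age = rng.choice(["50-54", "70-74"], size=n)
    sex = rng.choice(["female", "male"], size=n)
    eta = (
        beta_age * (age == "70-74")
        + beta_sex * (sex == "female")
        + interaction * ((age == "70-74") & (sex == "female"))
    )
    t1, t2 = 0.0, 1.5
    u = rng.random(n)
    c1 = expit(t1 - eta)
    c2 = expit(t2 - eta)
    cat = np.where(u < c1, "robust", np.where(u < c2, "pre_frail", "frail"))
    return _table(age, sex, [1] * n, cat)


def test_lrt_null_equals_alt_and_df():
    rng = np.random.default_rng(2)
    t = _simulate_po(rng, 2000, 0.5, 0.8, 0.0)
    null = fit_proportional_odds(t)
    stat, df, p = lrt_interaction(null, null)
    assert stat == 0.0 and df == 0 and p == 1.0

    alt = fit_proportional_odds(t, include_age_sex_interaction=True)
    stat, df, p = lrt_interaction(null, alt)
    # one age contrast present in the data -> one interaction indicator
    assert df == len(alt.params) - len(null.params)
    assert p > 0.01   # no true interaction simulated


def test_lrt_detects_strong_interaction():
    """With a large simulated age x sex interaction at n = 10^4 the test
    rejects at the 1% level in (nearly) every replicate."""
    hits = 0
    n_rep = 10
    for r in range(n_rep):
        rng = np.random.default_rng(100 + r)
        t = _simulate_po(rng, 10_000, 0.3, 0.6, 1.2)
        null = fit_proportional_odds(t)
        alt = fit_proportional_odds(t, include_age_sex_interaction=True)
        _, _, p = lrt_interaction(null, alt)
        if p < 0.01:
            hits += 1
    assert hits >= 9
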