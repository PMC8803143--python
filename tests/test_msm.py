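"""Weighted logistic MSM: fitting, standardization, interaction check."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import expit

from calsim import (
    MSMFit,
    SyntheticParams,
    generate_cohort,
    compute_weight_set,
    fit_msm,
    predict_prevalence,
)
from calsim import test_interaction as interaction_wald_test
from calsim.cohort import class_codes


@pytest.fixture(scope="module")
def fitted(default_cohort):
    wset = compute_weight_set(default_cohort)
    fit = fit_msm(default_cohort, wset.w_final, include_mediator=True)
    return default_cohort, wset, fit


def test_intercept_only_recovers_prevalence(default_cohort):
    """Uniform weights, exposure collapsed to one level -> fitted probability
    equals the sample prevalence."""
    df = default_cohort.copy()
    df["social_class"] = pd.Categorical(["high"] * len(df),
                                        categories=["high", "mid", "low"],
                                        ordered=True)
    fit = fit_msm(df, np.ones(len(df)))
    prev = predict_prevalence(fit, df)
    assert prev.prevalence_overall == pytest.approx(
        100 * default_cohort["obese11"].mean(), abs=1e-6
    )


def test_weight_scale_invariance(fitted):
    """Doubling all weights leaves the MLE unchanged."""
    cohort, wset, fit = fitted
    fit2 = fit_msm(cohort, 2.0 * wset.w_final, include_mediator=True)
    np.testing.assert_allclose(fit2.class_effects, fit.class_effects, atol=1e-8)
    assert fit2.mediator_coef == pytest.approx(fit.mediator_coef, abs=1e-10)


def test_coefficient_recovery_on_unconfounded_generator():
    """When the generating outcome model contains only class and intake (so
    the marginal and conditional models coincide — the logistic odds ratio is
    not collapsible over extra covariates), the weighted fit recovers the
    generating coefficients within sampling error."""
    base = SyntheticParams()
    cls2, slope = [], []
    for seed in range(5):
        params = SyntheticParams(n=50_000, seed=seed).replace(
            mediator=replace(base.mediator, beta_class=0.0),
            outcome=replace(base.outcome, alpha_birthweight=0.0,
                            alpha_health=0.0, alpha_activity=0.0,
                            alpha_tv=0.0, alpha_male=0.0),
        )
        df = generate_cohort(params)
        wset = compute_weight_set(df)
        fit = fit_msm(df, wset.w_final, include_mediator=True)
        cls2.append(fit.class_effects[2])
        slope.append(fit.mediator_coef)
    # 3-sigma bands on the 5-seed mean; per-seed SDs (0.045 for the class
    # contrast, 0.46e-4 for the intake slope) measured from a 20-replicate
    # calibration run at this n
    assert np.mean(cls2) == pytest.approx(2 * 0.12, abs=3 * 0.045 / np.sqrt(5))
    assert np.mean(slope) == pytest.approx(0.06 / 100,
                                           abs=3 * 0.46e-4 / np.sqrt(5))


def test_hand_computed_prevalences_from_fixed_coefficients():
    """Six-row cohort, hand-fixed coefficients: standardized prevalences
    equal spreadsheet-style averages of the logistic predictions."""
    df = pd.DataFrame({
        "social_class": pd.Categorical(
            ["high", "high", "mid", "mid", "low", "low"],
            categories=["high", "mid", "low"], ordered=True),
        "kcal7": [1500.0, 1700.0, 1600.0, 1800.0, 1550.0, 2000.0],
    })
    fit = MSMFit.from_params("social_class", intercept=-2.0,
                             class_effects=[0.0, 0.1, 0.3],
                             mediator_coef=0.0005, mediator_col="kcal7")
    prev = predict_prevalence(fit, df)
    lp = np.array([-2.0 + 0.0 + 0.0005 * 1500, -2.0 + 0.0 + 0.0005 * 1700,
                   -2.0 + 0.1 + 0.0005 * 1600, -2.0 + 0.1 + 0.0005 * 1800,
                   -2.0 + 0.3 + 0.0005 * 1550, -2.0 + 0.3 + 0.0005 * 2000])
    p = expit(lp)
    assert prev.prevalence_overall == pytest.approx(100 * p.mean(), abs=1e-10)
    assert prev.prevalence_by_class[0] == pytest.approx(100 * p[:2].mean(), abs=1e-10)
    assert prev.prevalence_by_class[2] == pytest.approx(100 * p[4:].mean(), abs=1e-10)


def test_identity_override_is_noop(fitted):
    cohort, _, fit = fitted
    base = predict_prevalence(fit, cohort)
    same = predict_prevalence(fit, cohort,
                              mediator_override=cohort["kcal7"].to_numpy())
    assert same.prevalence_overall == base.prevalence_overall
    assert same.mediator_values_used == "overridden"


def test_reduction_override_lowers_prevalence(fitted):
    """Positive mediator coefficient: 100 kcal less for everyone strictly
    lowers the standardized prevalence."""
    cohort, _, fit = fitted
    assert fit.mediator_coef > 0
    base = predict_prevalence(fit, cohort)
    less = predict_prevalence(
        fit, cohort, mediator_override=cohort["kcal7"].to_numpy() - 100.0
    )
    assert less.prevalence_overall < base.prevalence_overall


def test_override_length_mismatch_raises(fitted):
    cohort, _, fit = fitted
    with pytest.raises(ValueError, match="length"):
        predict_prevalence(fit, cohort, mediator_override=np.array([1700.0]))


def test_tde_cde_agree_when_mediator_unlinked_to_class():
    """If class does not shift intake, adding the mediator term leaves the
    by-class standardized prevalences essentially unchanged."""
    params = SyntheticParams(n=30_000, seed=23)
    params = params.replace(mediator=replace(params.mediator, beta_class=0.0))
    df = generate_cohort(params)
    wset = compute_weight_set(df)
    tde = predict_prevalence(fit_msm(df, wset.w1), df)
    cde = predict_prevalence(
        fit_msm(df, wset.w_final, include_mediator=True), df
    )
    for k in (0, 1, 2):
        assert cde.prevalence_by_class[k] == pytest.approx(
            tde.prevalence_by_class[k], abs=0.7
        )


def test_interaction_null_type_i_error():
    """Generator has no class x intake interaction: the Wald test rejects at
    roughly its nominal 5% level across repeated simulations."""
    rejections = 0
    reps = 40
    for seed in range(reps):
        df = generate_cohort(SyntheticParams(n=4_000, seed=1000 + seed))
        wset = compute_weight_set(df)
        res = interaction_wald_test(df, wset.w_final)
        rejections += res.include_interaction
    # binomial(40, 0.05): central 99% range
    assert 0 <= rejections <= 8


def test_interaction_detected_when_present():
    """A strong simulated interaction is picked up.  Built by flipping extra
    outcomes among high-intake low-class children."""
    df = generate_cohort(SyntheticParams(n=20_000, seed=77))
    rng = np.random.default_rng(5)
    cls = class_codes(df)
    hot = (cls == 2) & (df["kcal7"].to_numpy() > 1900)
    extra = hot & (rng.random(len(df)) < 0.25)
    df.loc[extra, "obese11"] = True
    df.loc[extra, "overweight_or_obese11"] = True
    wset = compute_weight_set(df)
    res = interaction_wald_test(df, wset.w_final)
    assert res.pvalue < 0.01 and res.include_interaction
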