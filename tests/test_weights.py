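"""IPW construction: hand-checked examples, stabilization, trimming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from calsim import (
    SyntheticParams,
    generate_cohort,
    compute_weight1,
    compute_weight2,
    compute_weight_set,
    stabilize_and_trim,
)
from calsim.weights import EstimationError
from calsim.synthetic import null_params


def _toy_cohort(counts):
    """Cohort from {(ethnicity, class_label): count}; other columns valid."""
    rows = []
    i = 0
    for (eth, cls), k in counts.items():
        for _ in range(k):
            rows.append(dict(
                child_id=f"x{i}", sex="male", social_class=cls, ethnicity=eth,
                birthweight_cat="mid", health_cat="healthy", activity_cat="mid",
                tv_cat="mid", kcal7=1700.0, low_income=0, obese7=0, obese11=0,
                overweight_or_obese11=0,
            ))
            i += 1
    from calsim import validate_cohort

    return validate_cohort(pd.DataFrame(rows))


def test_weight1_contingency_hand_computation():
    """2x2 stratum counts: (C=0, A=low) -> 0.45/0.30 = 1.5 and
    (C=1, A=high) -> 0.55/0.40 = 1.375, from plain contingency arithmetic."""
    counts = {
        ("white", "low"): 30, ("white", "high"): 70,   # C=0 stratum
        ("non_white", "low"): 60, ("non_white", "high"): 40,  # C=1 stratum
    }
    cohort = _toy_cohort(counts)
    for method in ("multinomial_logit", "saturated"):
        w = compute_weight1(cohort, method=method)
        is_low = cohort.social_class == "low"
        white = cohort.ethnicity == "white"
        np.testing.assert_allclose(w[is_low & white], 1.5, rtol=1e-6)
        np.testing.assert_allclose(w[~is_low & ~white], 0.55 / 0.40, rtol=1e-6)


def test_weight1_separation_raises():
    counts = {
        ("white", "low"): 30, ("white", "high"): 70,
        ("non_white", "high"): 50,  # no low-class children in this stratum
    }
    cohort = _toy_cohort(counts)
    with pytest.raises(EstimationError, match="non_white"):
        compute_weight1(cohort)


def test_weights_near_one_under_independence():
    """Exposure independent of confounders in the generator -> w1 ~ 1;
    mediator independent of confounders given exposure -> w2 ~ 1."""
    df = generate_cohort(null_params(n=20_000, seed=4, kcal_effect=True))
    w1 = compute_weight1(df)
    w2 = compute_weight2(df)
    assert np.abs(w1 - 1).max() < 0.2
    assert abs(w1.mean() - 1) < 0.02
    assert abs(w2.mean() - 1) < 0.02
    assert np.quantile(np.abs(w2 - 1), 0.95) < 0.15


def test_weight2_closed_form_density_ratio():
    """The implemented weight equals the normal density ratio computed
    independently from the two fitted (mean, sd) pairs."""
    df = generate_cohort(SyntheticParams(n=5_000, seed=8))
    w2 = compute_weight2(df)
    import statsmodels.formula.api as smf

    m = df["kcal7"].to_numpy()
    num = smf.ols("kcal7 ~ C(social_class)", df).fit()
    den = smf.ols(
        "kcal7 ~ C(social_class) + C(ethnicity) + C(birthweight_cat)"
        " + C(health_cat) + C(activity_cat) + C(tv_cat)", df
    ).fit()
    expected = (
        norm.pdf(m, num.fittedvalues, np.sqrt(num.mse_resid))
        / norm.pdf(m, den.fittedvalues, np.sqrt(den.mse_resid))
    )
    np.testing.assert_allclose(w2, expected, rtol=1e-10)


def test_weight2_location_equivariance():
    """Adding a constant to every intake leaves the density-ratio weight
    unchanged (both fitted means absorb the shift)."""
    df = generate_cohort(SyntheticParams(n=3_000, seed=9))
    w_ref = compute_weight2(df)
    shifted = df.copy()
    shifted["kcal7"] = shifted["kcal7"] + 250.0
    np.testing.assert_allclose(compute_weight2(shifted), w_ref, rtol=1e-8)


def test_stabilized_means_near_one_at_n10000():
    df = generate_cohort(SyntheticParams(n=10_000, seed=13))
    wset = compute_weight_set(df)
    assert abs(wset.w1.mean() - 1) < 0.05
    assert abs(wset.w2.mean() - 1) < 0.05


def test_trim_matches_sort_and_cap_oracle():
    """Winsorization equals an independent sort/read-percentile/cap oracle."""
    rng = np.random.default_rng(0)
    w = rng.lognormal(0, 0.8, 200)
    trimmed, (lo, hi), n_lo, n_hi = stabilize_and_trim(w, 1, 99)

    srt = np.sort(w)
    # order-statistic bounds computed by hand: floor rank for the lower cut,
    # ceil rank for the upper cut
    exp_lo = srt[int(np.floor(0.01 * (len(srt) - 1)))]
    exp_hi = srt[int(np.ceil(0.99 * (len(srt) - 1)))]
    assert lo == pytest.approx(exp_lo, rel=1e-12)
    assert hi == pytest.approx(exp_hi, rel=1e-12)
    expected = np.minimum(np.maximum(w, exp_lo), exp_hi)
    np.testing.assert_allclose(trimmed, expected, rtol=1e-12)
    assert n_lo == (w < exp_lo).sum() and n_hi == (w > exp_hi).sum()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=400),
       st.floats(0, 20), st.floats(80, 100))
def test_trim_properties(ws, lo_pct, hi_pct):
    """Idempotence, bound respect, and no-op at (0, 100)."""
    if not lo_pct < hi_pct:
        return
    w = np.asarray(ws)
    t1, bounds, _, _ = stabilize_and_trim(w, lo_pct, hi_pct)
    t2, _, _, _ = stabilize_and_trim(t1, lo_pct, hi_pct)
    np.testing.assert_allclose(t1, t2, rtol=1e-9, atol=1e-12)
    if np.unique(w).size >= 2:
        assert t1.min() >= bounds[0] - 1e-12 and t1.max() <= bounds[1] + 1e-12
    ident, _, nl, nh = stabilize_and_trim(w, 0, 100)
    np.testing.assert_allclose(ident, w)
    assert nl == 0 and nh == 0


def test_all_equal_weights_untouched():
    w = np.ones(50)
    trimmed, _, n_lo, n_hi = stabilize_and_trim(w, 1, 99)
    np.testing.assert_array_equal(trimmed, w)
    assert n_lo == 0 and n_hi == 0


def test_weight_set_invariants(default_cohort):
    wset = compute_weight_set(default_cohort)
    assert np.all(wset.w_final > 0) and np.all(np.isfinite(wset.w_final))
    assert wset.w_final.min() >= wset.trim_bounds[0] - 1e-12
    assert wset.w_final.max() <= wset.trim_bounds[1] + 1e-12
    d = wset.diagnostics()
    assert d["n_trimmed_low"] + d["n_trimmed_high"] > 0
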