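"""Intervention scenarios: printed-value arithmetic, masks, uptake, noise,
lower bound."""

import numpy as np
import pytest

from calsim import (
    EARTable,
    ScenarioSpec,
    SyntheticParams,
    apply_scenario,
    assign_uptake,
    compute_scenario1_shift,
    eligibility_mask,
    generate_cohort,
    preset_scenarios,
)

PUBLISHED_MEDIANS = {"male": 1732.4, "female": 1654.1}


def test_shift_to_ear_published_arithmetic():
    """From the published medians and EARs: boys need 83.4 kcal (4.8%) less,
    girls 124.1 kcal (7.5%), a 6.1% overall reduction at the published sex
    shares."""
    s = compute_scenario1_shift(PUBLISHED_MEDIANS,
                                sex_shares={"male": 0.519, "female": 0.481})
    assert s.reduction_by_sex["male"] == pytest.approx(83.4, abs=0.05)
    assert s.reduction_by_sex["female"] == pytest.approx(124.1, abs=0.05)
    assert round(s.percent_by_sex["male"], 1) == 4.8
    assert round(s.percent_by_sex["female"], 1) == 7.5
    assert round(s.overall_percent, 1) == 6.1


def test_shift_floors_at_zero():
    s = compute_scenario1_shift({"male": 1649.0, "female": 1200.0})
    assert s.reduction_by_sex["male"] == 0.0
    assert s.reduction_by_sex["female"] == 0.0  # median below EAR
    assert s.overall_percent == 0.0


def test_eligibility_rules(default_cohort):
    spec_all = ScenarioSpec(name="x", eligibility="all")
    assert eligibility_mask(default_cohort, spec_all).all()

    spec_li = ScenarioSpec(name="x", eligibility="low_income")
    np.testing.assert_array_equal(
        eligibility_mask(default_cohort, spec_li),
        default_cohort["low_income"].to_numpy(),
    )

    spec_ob = ScenarioSpec(name="x", eligibility="obese7")
    mask = eligibility_mask(default_cohort, spec_ob)
    assert mask.sum() == default_cohort["obese7"].sum()

    none_obese = default_cohort.assign(obese7=False)
    assert eligibility_mask(none_obese, spec_ob).sum() == 0


def test_above_ear_is_strict(default_cohort):
    """A boy consuming exactly the EAR is not eligible."""
    df = default_cohort.copy()
    df.loc[df.index[0], "sex"] = "male"
    df.loc[df.index[0], "kcal7"] = 1649.0
    mask = eligibility_mask(df, ScenarioSpec(name="x", eligibility="above_ear"))
    assert not mask[0]
    boys_above = (df["sex"] == "male") & (df["kcal7"] > 1649.0)
    assert mask[(df["sex"] == "male").to_numpy()].sum() == boys_above.sum()


def test_uptake_bounds_and_share():
    mask = np.ones(100_000, dtype=bool)
    assert assign_uptake(mask, 1.0, 0).all()
    assert not assign_uptake(mask, 0.0, 0).any()
    treated = assign_uptake(mask, 0.75, 5)
    assert treated.mean() == pytest.approx(0.75, abs=0.005)
    # ineligible children can never be treated
    half = np.zeros(1000, dtype=bool)
    half[:500] = True
    assert not assign_uptake(half, 0.9, 1)[500:].any()


def test_uptake_deterministic_given_seed(default_cohort):
    spec = ScenarioSpec(name="x", eligibility="all", uptake=0.5, seed=11)
    a = apply_scenario(default_cohort, spec)
    b = apply_scenario(default_cohort, spec)
    np.testing.assert_array_equal(a.treated, b.treated)
    np.testing.assert_array_equal(a.kcal_modified, b.kcal_modified)


def test_truncate_at_ear_postcondition(default_cohort):
    """After the truncation scenario every child is at or below the
    sex-specific EAR, and children already below it are untouched."""
    spec = [s for s in preset_scenarios() if s.effect == "truncate_at_ear"][0]
    out = apply_scenario(default_cohort, spec)
    ear = EARTable().per_child(default_cohort)
    kcal = default_cohort["kcal7"].to_numpy()
    assert (out.kcal_modified <= ear + 1e-9).all()
    assert out.prop_leq_ear_by_sex["male"] == 100.0
    assert out.prop_leq_ear_by_sex["female"] == 100.0
    below = kcal < ear
    np.testing.assert_array_equal(out.kcal_modified[below], kcal[below])


def test_zero_uptake_is_identity(default_cohort):
    spec = ScenarioSpec(name="x", eligibility="all", uptake=0.0,
                        effect="proportional_reduction")
    out = apply_scenario(default_cohort, spec)
    np.testing.assert_array_equal(out.kcal_modified,
                                  default_cohort["kcal7"].to_numpy())
    assert out.summary["n_treated"] == 0


def test_untreated_children_unchanged(default_cohort):
    spec = ScenarioSpec(name="x", eligibility="low_income", uptake=0.6,
                        effect="proportional_reduction", seed=2)
    out = apply_scenario(default_cohort, spec)
    kcal = default_cohort["kcal7"].to_numpy()
    np.testing.assert_array_equal(out.kcal_modified[~out.treated],
                                  kcal[~out.treated])


def test_proportional_reduction_hand_value():
    """21.3% off 2000 kcal with no noise = 1574.0 kcal (above the bound)."""
    df = generate_cohort(SyntheticParams(n=2_000, seed=14))
    df.loc[df.index[0], "kcal7"] = 2000.0
    spec = ScenarioSpec(name="x", eligibility="all", uptake=1.0,
                        effect="proportional_reduction",
                        reduction_fraction=0.213, noise_cv=0.0)
    out = apply_scenario(df, spec)
    assert out.kcal_modified[0] == pytest.approx(2000.0 * (1 - 0.213), abs=1e-9)
    assert out.kcal_modified[0] == pytest.approx(1574.0, abs=0.05)


def test_noise_mean_matches_intended_reduction():
    """Mean realized reduction among treated tracks the intended mean."""
    df = generate_cohort(SyntheticParams(n=40_000, seed=15))
    spec = ScenarioSpec(name="x", eligibility="all", uptake=1.0,
                        effect="proportional_reduction",
                        reduction_fraction=0.213, noise_cv=0.25, seed=3)
    out = apply_scenario(df, spec)
    kcal = df["kcal7"].to_numpy()
    # restrict to children safely above the lower bound so capping is rare
    safe = kcal > out.lower_bound / (1 - 0.213 * 2)
    realized = (kcal - out.kcal_modified)[safe & out.treated]
    intended = 0.213 * kcal[safe & out.treated]
    assert realized.mean() / intended.mean() == pytest.approx(1.0, abs=0.02)


def test_lower_bound_rules(default_cohort):
    """Children starting below the pooled 2-SD bound are never reduced; no
    treated child starting above it ends below it; intake never increases."""
    df = default_cohort
    kcal = df["kcal7"].to_numpy()
    spec = ScenarioSpec(name="x", eligibility="all", uptake=1.0,
                        effect="proportional_reduction",
                        reduction_fraction=0.5, noise_cv=0.6, seed=4)
    out = apply_scenario(df, spec)
    b = out.lower_bound
    assert b == pytest.approx(kcal.mean() - 2 * kcal.std(ddof=1), rel=1e-12)
    below = kcal < b
    np.testing.assert_array_equal(out.kcal_modified[below], kcal[below])
    assert (out.kcal_modified[~below] >= b - 1e-9).all()
    assert (out.kcal_modified <= kcal + 1e-9).all()
    assert (out.kcal_modified > 0).all()


def test_spec_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        ScenarioSpec(name="x", eligibility="everyone")
    with pytest.raises(ValueError):
        ScenarioSpec(name="x", uptake=1.4)
    spec = preset_scenarios(seed=9)[1]
    path = tmp_path / "s.yaml"
    spec.to_yaml(path)
    assert ScenarioSpec.from_yaml(path) == spec
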