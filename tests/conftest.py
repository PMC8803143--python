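import numpy as np
import pandas as pd
import pytest

from calsim import SyntheticParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized default synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticParams(n=10_000, seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """n=50k default cohort for marginal-structure checks."""
    return generate_cohort(SyntheticParams(n=50_000, seed=7))


@pytest.fixture()
def tiny_cohort():
    """Hand-sized cohort for serialization and arithmetic tests."""
    return generate_cohort(SyntheticParams(n=5, seed=3))


def make_binary_confounder_cohort(n=400, seed=0, p_y=None):
    """Cohort with one binary confounder (ethnicity) driving class, for
    saturated-model equivalence tests; other columns filled in validly."""
    rng = np.random.default_rng(seed)
    eth = rng.random(n) < 0.4
    # class distribution differs by ethnicity stratum
    p_cls = np.where(eth[:, None], [[0.2, 0.3, 0.5]], [[0.5, 0.3, 0.2]])
    u = rng.random(n)
    cls = (u[:, None] > np.cumsum(p_cls, axis=1)).sum(axis=1)
    kcal = rng.normal(1700, 300, n).clip(500)
    p = 0.1 + 0.05 * cls + 0.1 * eth
    y = rng.random(n) < p
    df = pd.DataFrame({
        "child_id": [f"t{i}" for i in range(n)],
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "social_class": pd.Categorical.from_codes(cls, ["high", "mid", "low"],
                                                  ordered=True),
        "ethnicity": np.where(eth, "non_white", "white"),
        "birthweight_cat": "mid",
        "health_cat": "healthy",
        "activity_cat": "mid",
        "tv_cat": "mid",
        "kcal7": kcal,
        "low_income": False,
        "obese7": False,
        "obese11": y,
        "overweight_or_obese11": y,
    })
    from calsim import validate_cohort

    return validate_cohort(df)
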