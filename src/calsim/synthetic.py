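"""Synthetic ALSPAC-like cohort generator with known causal ground truth.

The real study cohort is access-controlled, so analyses here run on synthetic
cohorts whose *marginal* structure matches the published descriptive table of
the analytic sample (sex split, maternal social-class distribution, ethnicity,
intermediate confounders, median daily energy intake, obesity prevalence at 7
and 11, low-income share) and whose *causal* structure is fully specified, so
that estimators can be checked against exact oracles.

Generating model (all confounders categorical, so the confounder lattice is
finite and oracles can enumerate it exactly):

- sex ~ Bernoulli(p_male); social class A ~ p_class (codes 0=high,1=mid,2=low)
- ethnicity C | A and each intermediate confounder L | A categorical with mild
  class gradients calibrated to the published marginals
- mediator M (kcal/day) is log-normal: log M = mu(sex) + b_A A + b_L L + s eps;
  sex-specific intercepts are calibrated so the sex medians hit the published
  1732.4 (boys) / 1654.1 (girls); the class gradient is weakly *positive
  toward the high class*, reproducing the study's inverse relationship
  between intake and disadvantage
- outcome Y ~ Bernoulli(logit^-1(a0 + aA A + aM M/100 + aL L)); the combined
  overweight/obesity indicator uses the same linear predictor with a positive
  intercept shift and a shared uniform draw, so Y=1 implies the combined
  indicator is 1
- targeting flags: low_income ~ Bernoulli(p | A) (33.7% overall, concentrated
  in the low class); obese7 ~ Bernoulli(logit^-1 of its own model in A and M)
  (9.3% overall)

Intercepts marked "calibrated" below were fixed once by bisection on simulated
prevalence under the default coefficients (see docs/methods.md).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CATEGORIES, EARTable, validate_cohort

__all__ = [
    "MediatorModel",
    "OutcomeModel",
    "TargetingModel",
    "SyntheticParams",
    "generate_cohort",
    "true_cde_oracle",
    "true_cde_curve",
    "true_tde_oracle",
    "null_params",
]

_CLASSES = (0, 1, 2)  # high, mid, low (disadvantage code)


@dataclass(frozen=True)
class MediatorModel:
    """Log-normal model for daily energy intake at age 7 (kcal/day).

    ``beta_*`` act on the log scale; ``sigma_log`` ~0.20 corresponds to a
    coefficient of variation of about 20%, typical of diet-diary intake.
    """

    median_kcal_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1732.4, "female": 1654.1}
    )
    beta_class: float = -0.008  # log-kcal per unit disadvantage (<0: high class eats most)
    beta_birthweight: float = 0.012  # per ordinal level
    beta_health: float = -0.010  # unwell vs healthy
    beta_activity: float = 0.005  # per ordinal level
    beta_tv: float = 0.010  # per ordinal level
    sigma_log: float = 0.20


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for obesity at age 11.

    ``alpha_kcal`` is per 100 kcal/day.  ``alpha0`` calibrated to an 18.3%
    marginal prevalence; ``delta_overweight`` is the intercept shift giving
    the combined overweight/obesity indicator its 34.4% marginal prevalence.
    """

    alpha0: float = -2.8306
    alpha_class: float = 0.12  # per unit disadvantage
    alpha_kcal: float = 0.06  # per 100 kcal
    alpha_birthweight: float = 0.15
    alpha_health: float = 0.10
    alpha_activity: float = -0.08
    alpha_tv: float = 0.10
    alpha_male: float = 0.0
    delta_overweight: float = 0.863


@dataclass(frozen=True)
class TargetingModel:
    """Models for the intervention-targeting flags."""

    #: P(low income | class); weighted by the class mix this gives 33.7% overall.
    p_low_income_by_class: tuple[float, float, float] = (0.13, 0.32, 0.62)
    obese7_alpha0: float = -3.4531  # calibrated to 9.3% marginal prevalence
    obese7_alpha_class: float = 0.12
    obese7_alpha_kcal: float = 0.06  # per 100 kcal


def _scaled(rows: Sequence[Sequence[float]]) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(r) for r in rows)


@dataclass(frozen=True)
class SyntheticParams:
    """Full ground-truth data-generating configuration.

    Per-class probability tables are indexed by disadvantage code
    (0=high, 1=mid, 2=low); category order follows
    :data:`calsim.cohort.CATEGORIES`.  The defaults reproduce the published
    marginals of the analytic sample within Monte-Carlo error.
    """

    n: int = 10_000
    seed: int = 0
    p_male: float = 0.519
    p_class: tuple[float, float, float] = (0.316, 0.427, 0.257)
    p_nonwhite_by_class: tuple[float, float, float] = (0.030, 0.045, 0.056)
    p_birthweight_by_class: tuple[tuple[float, ...], ...] = _scaled(
        [(0.120, 0.725, 0.155), (0.130, 0.725, 0.145), (0.150, 0.720, 0.130)]
    )
    p_unwell_by_class: tuple[float, float, float] = (0.022, 0.029, 0.038)
    p_activity_by_class: tuple[tuple[float, ...], ...] = _scaled(
        [(0.055, 0.645, 0.300), (0.072, 0.668, 0.260), (0.093, 0.681, 0.226)]
    )
    p_tv_by_class: tuple[tuple[float, ...], ...] = _scaled(
        [(0.090, 0.815, 0.095), (0.075, 0.810, 0.115), (0.060, 0.801, 0.139)]
    )
    mediator: MediatorModel = field(default_factory=MediatorModel)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    targeting: TargetingModel = field(default_factory=TargetingModel)
    #: P(education label equals the social-class label); otherwise redrawn
    #: independently from ``p_class``.
    p_education_match: float = 0.75
    ear: EARTable = field(default_factory=EARTable)

    def __post_init__(self):
        if self.n < 0:
            raise ValueError(f"cohort size n must be >= 0, got {self.n}")
        if abs(sum(self.p_class) - 1.0) > 1e-8:
            raise ValueError("p_class must sum to 1")
        if self.mediator.sigma_log <= 0:
            raise ValueError("mediator sigma_log must be > 0")
        for name in ("p_birthweight_by_class", "p_activity_by_class", "p_tv_by_class"):
            for row in getattr(self, name):
                if abs(sum(row) - 1.0) > 1e-8:
                    raise ValueError(f"rows of {name} must sum to 1")

    # -- convenience ---------------------------------------------------------
    def replace(self, **kw) -> "SyntheticParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ear"] = dict(self.ear.ear_by_sex)
        return d


# --------------------------------------------------------------------------
# internal linear predictors
# --------------------------------------------------------------------------

def _mediator_cov(params: SyntheticParams, cls, bw, unwell, act, tv):
    m = params.mediator
    return (
        m.beta_class * cls
        + m.beta_birthweight * bw
        + m.beta_health * unwell
        + m.beta_activity * act
        + m.beta_tv * tv
    )


def _mediator_intercepts(params: SyntheticParams) -> dict[str, float]:
    """Sex-specific log-scale intercepts hitting the target sex medians.

    The covariate contribution is small and symmetric enough that the median
    of the log-normal mixture is exp(intercept + E[covariates]) to first
    order; the expectation is taken exactly over the class/confounder lattice.
    """
    shift = 0.0
    for cls, p_cls in zip(_CLASSES, params.p_class):
        for bw, p_bw in enumerate(params.p_birthweight_by_class[cls]):
            for act, p_act in enumerate(params.p_activity_by_class[cls]):
                for tv, p_tv in enumerate(params.p_tv_by_class[cls]):
                    for unwell, p_h in (
                        (0, 1 - params.p_unwell_by_class[cls]),
                        (1, params.p_unwell_by_class[cls]),
                    ):
                        shift += (
                            p_cls * p_bw * p_act * p_tv * p_h
                            * _mediator_cov(params, cls, bw, unwell, act, tv)
                        )
    return {
        sex: float(np.log(med) - shift)
        for sex, med in params.mediator.median_kcal_by_sex.items()
    }


def _outcome_lp(params: SyntheticParams, cls, kcal, bw, unwell, act, tv, male):
    o = params.outcome
    return (
        o.alpha0
        + o.alpha_class * cls
        + o.alpha_kcal * kcal / 100.0
        + o.alpha_birthweight * bw
        + o.alpha_health * unwell
        + o.alpha_activity * act
        + o.alpha_tv * tv
        + o.alpha_male * male
    )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_cohort(params: SyntheticParams) -> pd.DataFrame:
    """Draw a complete synthetic cohort; bit-identical for a given seed."""
    n = params.n
    rng = np.random.default_rng(params.seed)

    male = rng.random(n) < params.p_male
    cls = rng.choice(3, size=n, p=np.asarray(params.p_class))

    p_nw = np.asarray(params.p_nonwhite_by_class)[cls]
    nonwhite = rng.random(n) < p_nw

    def _draw_cat(table):
        probs = np.asarray(table)[cls]  # n x k
        u = rng.random(n)
        return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    bw = _draw_cat(params.p_birthweight_by_class)
    act = _draw_cat(params.p_activity_by_class)
    tv = _draw_cat(params.p_tv_by_class)
    unwell = rng.random(n) < np.asarray(params.p_unwell_by_class)[cls]

    intercepts = _mediator_intercepts(params)
    mu = np.where(male, intercepts["male"], intercepts["female"])
    mu = mu + _mediator_cov(params, cls, bw, unwell.astype(int), act, tv)
    kcal = np.exp(mu + params.mediator.sigma_log * rng.standard_normal(n))

    lp = _outcome_lp(params, cls, kcal, bw, unwell.astype(int), act, tv,
                     male.astype(int))
    u_y = rng.random(n)
    obese11 = u_y < expit(lp)
    owob11 = u_y < expit(lp + params.outcome.delta_overweight)

    t = params.targeting
    low_income = rng.random(n) < np.asarray(t.p_low_income_by_class)[cls]
    lp7 = t.obese7_alpha0 + t.obese7_alpha_class * cls + t.obese7_alpha_kcal * kcal / 100.0
    obese7 = rng.random(n) < expit(lp7)

    edu = cls.copy()
    remix = rng.random(n) >= params.p_education_match
    edu[remix] = rng.choice(3, size=int(remix.sum()), p=np.asarray(params.p_class))

    def _cat(codes, col):
        cats = CATEGORIES[col]
        return pd.Categorical.from_codes(
            np.asarray(codes, dtype=int), categories=list(cats),
            ordered=col in {"social_class", "birthweight_cat", "activity_cat",
                            "tv_cat", "education"},
        )

    df = pd.DataFrame(
        {
            "child_id": [f"c{i:07d}" for i in range(n)],
            "sex": _cat(1 - male.astype(int), "sex"),
            "social_class": _cat(cls, "social_class"),
            "ethnicity": _cat(nonwhite.astype(int), "ethnicity"),
            "birthweight_cat": _cat(bw, "birthweight_cat"),
            "health_cat": _cat(unwell.astype(int), "health_cat"),
            "activity_cat": _cat(act, "activity_cat"),
            "tv_cat": _cat(tv, "tv_cat"),
            "kcal7": kcal,
            "low_income": low_income,
            "obese7": obese7,
            "obese11": obese11,
            "overweight_or_obese11": owob11,
            "education": _cat(edu, "education"),
        }
    )
    return validate_cohort(df, coerce=False)


# --------------------------------------------------------------------------
# exact oracles (finite confounder lattice)
# --------------------------------------------------------------------------

def _lattice(params: SyntheticParams, cls: int):
    """Joint confounder distribution under do(class=cls).

    Yields (probability, dict of covariate codes) over
    sex x ethnicity x birthweight x health x activity x tv (216 cells).
    """
    p_h = params.p_unwell_by_class[cls]
    for male, p_sex in ((1, params.p_male), (0, 1 - params.p_male)):
        for nw, p_nw in ((1, params.p_nonwhite_by_class[cls]),
                         (0, 1 - params.p_nonwhite_by_class[cls])):
            for bw, act, tv, unwell in itertools.product(
                range(3), range(3), range(3), (0, 1)
            ):
                p = (
                    p_sex * p_nw
                    * params.p_birthweight_by_class[cls][bw]
                    * params.p_activity_by_class[cls][act]
                    * params.p_tv_by_class[cls][tv]
                    * (p_h if unwell else 1 - p_h)
                )
                yield p, dict(male=male, nonwhite=nw, bw=bw, act=act, tv=tv,
                              unwell=unwell)


def true_cde_curve(params: SyntheticParams, cls: int, kcal) -> np.ndarray:
    """Exact P(Y=1 | do(class=cls), do(kcal=m)) for an array of m values.

    Averages the outcome model over the exact confounder-lattice distribution
    under the class intervention.
    """
    kcal = np.atleast_1d(np.asarray(kcal, dtype=float))
    out = np.zeros_like(kcal)
    for p, cell in _lattice(params, cls):
        out += p * expit(
            _outcome_lp(params, cls, kcal, cell["bw"], cell["unwell"],
                        cell["act"], cell["tv"], cell["male"])
        )
    return out


def true_cde_oracle(
    params: SyntheticParams,
    class_values: tuple[int, int] = (0, 2),
    m_fixed: float = 1700.0,
) -> tuple[float, float]:
    """Exact standardized outcome probabilities under a controlled mediator.

    Returns ``(P(Y=1 | do(A=a1), do(M=m)), P(Y=1 | do(A=a2), do(M=m)))`` for
    the two class levels in ``class_values``, by exact enumeration of the
    finite confounder lattice.
    """
    a1, a2 = class_values
    return (
        float(true_cde_curve(params, a1, m_fixed)[0]),
        float(true_cde_curve(params, a2, m_fixed)[0]),
    )


def true_tde_oracle(params: SyntheticParams, cls: int, gh_points: int = 48) -> float:
    """Exact P(Y=1 | do(class=cls)) with the mediator at its natural value.

    Integrates the outcome model over the log-normal mediator distribution of
    each lattice cell by Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(gh_points)
    weights = weights / np.sqrt(2 * np.pi)
    intercepts = _mediator_intercepts(params)
    s = params.mediator.sigma_log
    total = 0.0
    for p, cell in _lattice(params, cls):
        mu = (
            intercepts["male" if cell["male"] else "female"]
            + _mediator_cov(params, cls, cell["bw"], cell["unwell"],
                            cell["act"], cell["tv"])
        )
        m = np.exp(mu + s * nodes)
        probs = expit(
            _outcome_lp(params, cls, m, cell["bw"], cell["unwell"],
                        cell["act"], cell["tv"], cell["male"])
        )
        total += p * float(weights @ probs)
    return total


def null_params(n: int = 10_000, seed: int = 0,
                kcal_effect: bool = False) -> SyntheticParams:
    """Parameters with every class-linked pathway switched off.

    Class no longer affects the mediator, the outcome, ethnicity or the
    intermediate confounders, so all classes share one outcome distribution.
    With ``kcal_effect=False`` (default) the mediator does not affect the
    outcome either, so calorie interventions are inert — the full null used
    by negative-control checks.
    """
    base = SyntheticParams()
    flat = lambda rows: _scaled([rows] * 3)  # noqa: E731
    # class-marginal mixtures of the default per-class tables
    mix = lambda tbl: tuple(  # noqa: E731
        float(np.dot(base.p_class, [row[k] for row in tbl]))
        for k in range(len(tbl[0]))
    )
    return base.replace(
        n=n,
        seed=seed,
        p_nonwhite_by_class=(0.043, 0.043, 0.043),
        p_birthweight_by_class=flat(mix(base.p_birthweight_by_class)),
        p_activity_by_class=flat(mix(base.p_activity_by_class)),
        p_tv_by_class=flat(mix(base.p_tv_by_class)),
        p_unwell_by_class=(0.029, 0.029, 0.029),
        mediator=replace(base.mediator, beta_class=0.0),
        outcome=replace(
            base.outcome,
            alpha_class=0.0,
            alpha_kcal=base.outcome.alpha_kcal if kcal_effect else 0.0,
        ),
        targeting=replace(base.targeting, obese7_alpha_class=0.0),
    )
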