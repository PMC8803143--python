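"""Weighted logistic marginal structural models and marginal standardization.

The total direct effect (TDE) model regresses the binary outcome on the
categorical exposure alone, weighted by the stabilized exposure weight; the
controlled direct effect (CDE) model adds the continuous mediator and uses
the product weight.  Prevalences are obtained by marginal standardization:
per-child predicted probabilities at each child's own covariates (with the
mediator optionally overridden, which is how intervention scenarios are
evaluated), averaged overall and within exposure group, x100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import class_codes

__all__ = ["MSMFit", "MSMResult", "fit_msm", "predict_prevalence",
           "test_interaction", "InteractionTest"]


@dataclass
class MSMFit:
    """A fitted weighted logistic MSM.

    ``intercept``, ``class_effects`` (one per exposure level, reference 0),
    ``mediator_coef`` and ``interaction_coefs`` fully determine the
    prediction surface; ``results`` holds the underlying statsmodels fit
    when the model was estimated from data.
    """

    exposure_col: str
    n_levels: int
    intercept: float
    class_effects: np.ndarray  # length n_levels, [0] == 0 (reference)
    mediator_coef: float | None = None
    mediator_col: str | None = None
    interaction_coefs: np.ndarray | None = None  # per level, [0] == 0
    exposure_as: str = "categorical"
    results: object | None = None

    @classmethod
    def from_params(cls, exposure_col: str, intercept: float,
                    class_effects: Sequence[float],
                    mediator_coef: float | None = None,
                    mediator_col: str | None = None,
                    interaction_coefs: Sequence[float] | None = None,
                    exposure_as: str = "categorical") -> "MSMFit":
        """Build a prediction surface from hand-fixed coefficients."""
        ce = np.asarray(class_effects, dtype=float)
        ic = None if interaction_coefs is None else np.asarray(interaction_coefs, float)
        return cls(exposure_col=exposure_col, n_levels=len(ce),
                   intercept=float(intercept), class_effects=ce,
                   mediator_coef=mediator_coef, mediator_col=mediator_col,
                   interaction_coefs=ic, exposure_as=exposure_as)

    @property
    def include_mediator(self) -> bool:
        return self.mediator_coef is not None

    def coefficients(self) -> dict[str, float]:
        out = {"intercept": self.intercept}
        if self.exposure_as == "continuous":
            out[f"{self.exposure_col}_slope"] = float(self.class_effects[1])
        else:
            for k in range(1, self.n_levels):
                out[f"{self.exposure_col}[{k}]"] = float(self.class_effects[k])
        if self.include_mediator:
            out[f"{self.mediator_col}_per_kcal"] = float(self.mediator_coef)
        if self.interaction_coefs is not None:
            for k in range(1, self.n_levels):
                out[f"{self.exposure_col}[{k}]:{self.mediator_col}"] = float(
                    self.interaction_coefs[k]
                )
        return out

    def linear_predictor(self, cls: np.ndarray, m: np.ndarray | None) -> np.ndarray:
        if self.exposure_as == "continuous":
            lp = self.intercept + self.class_effects[1] * cls
        else:
            lp = self.intercept + self.class_effects[cls]
        if self.include_mediator:
            if m is None:
                raise ValueError("model includes the mediator; values required")
            lp = lp + self.mediator_coef * m
            if self.interaction_coefs is not None:
                lp = lp + self.interaction_coefs[cls] * m
        return lp

    def predict(self, cls: np.ndarray, m: np.ndarray | None = None) -> np.ndarray:
        return expit(self.linear_predictor(np.asarray(cls), m))


@dataclass
class MSMResult:
    """Standardized prevalence summary of one fitted MSM."""

    effect_type: str  # "TDE" or "CDE"
    coefficients: Mapping[str, float]
    prevalence_overall: float  # percent
    prevalence_by_class: dict[int, float]  # percent, keyed by class code
    mediator_values_used: str = "observed"
    meta: dict = field(default_factory=dict)


def _build_design(cls: np.ndarray, m: np.ndarray | None, n_levels: int,
                  interaction: bool, exposure_as: str):
    cols = [np.ones_like(cls, dtype=float)]
    names = ["intercept"]
    if exposure_as == "continuous":
        cols.append(cls.astype(float))
        names.append("class")
    else:
        for k in range(1, n_levels):
            cols.append((cls == k).astype(float))
            names.append(f"class[{k}]")
    if m is not None:
        cols.append(m)
        names.append("mediator")
        if interaction:
            if exposure_as == "continuous":
                cols.append(cls.astype(float) * m)
                names.append("class:mediator")
            else:
                for k in range(1, n_levels):
                    cols.append((cls == k).astype(float) * m)
                    names.append(f"class[{k}]:mediator")
    return np.column_stack(cols), names


def fit_msm(
    cohort: pd.DataFrame,
    weights: np.ndarray,
    outcome_col: str = "obese11",
    exposure_col: str = "social_class",
    include_mediator: bool = False,
    mediator_col: str = "kcal7",
    include_interaction: bool = False,
    exposure_as: str = "categorical",
    tol: float = 1e-8,
    maxiter: int = 200,
) -> MSMFit:
    """Fit the weighted logistic MSM of the outcome on exposure (+ mediator).

    Weighted maximum likelihood via IRLS (statsmodels GLM with frequency
    weights); convergence tolerance ``tol`` on the deviance.  Raises on
    non-convergence or perfect separation.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(cohort):
        raise ValueError("weights not aligned to cohort rows")
    y = cohort[outcome_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome_col!r} must be binary")
    cls = class_codes(cohort, exposure_col)
    n_levels = int(cls.max()) + 1
    m = cohort[mediator_col].to_numpy(dtype=float) if include_mediator else None

    exog, names = _build_design(cls, m, n_levels, include_interaction, exposure_as)
    model = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=weights)
    res = model.fit(maxiter=maxiter, tol=tol, cov_type="HC1")
    if not res.converged:
        raise RuntimeError(
            f"MSM did not converge in {maxiter} IRLS iterations "
            f"(deviance history: {getattr(res, 'fit_history', {}).get('deviance', [])[-5:]})"
        )
    if np.abs(res.params).max() > 50:
        raise RuntimeError("perfect separation suspected: |coefficient| > 50")

    params = dict(zip(names, res.params))
    if exposure_as == "continuous":
        class_effects = np.array([0.0, params["class"]])
    else:
        class_effects = np.zeros(n_levels)
        for k in range(1, n_levels):
            class_effects[k] = params[f"class[{k}]"]
    interaction = None
    if include_mediator and include_interaction:
        if exposure_as == "continuous":
            interaction = np.array([0.0, params["class:mediator"]])
        else:
            interaction = np.zeros(n_levels)
            for k in range(1, n_levels):
                interaction[k] = params[f"class[{k}]:mediator"]
    return MSMFit(
        exposure_col=exposure_col, n_levels=n_levels,
        intercept=params["intercept"], class_effects=class_effects,
        mediator_coef=params.get("mediator"),
        mediator_col=mediator_col if include_mediator else None,
        interaction_coefs=interaction, exposure_as=exposure_as, results=res,
    )


def predict_prevalence(
    fit: MSMFit,
    cohort: pd.DataFrame,
    mediator_override: np.ndarray | None = None,
) -> MSMResult:
    """Marginally standardized prevalences (percent), overall and by class.

    Per-child probabilities are predicted at each child's own covariates;
    ``mediator_override`` replaces the observed mediator values (same length
    as the cohort), which is how intervention scenarios are scored without
    refitting the outcome model.
    """
    cls = class_codes(cohort, fit.exposure_col)
    m = None
    if fit.include_mediator:
        if mediator_override is not None:
            m = np.asarray(mediator_override, dtype=float)
            if len(m) != len(cohort):
                raise ValueError("mediator_override length mismatch")
        else:
            m = cohort[fit.mediator_col].to_numpy(dtype=float)
    elif mediator_override is not None:
        raise ValueError("model has no mediator term; override is meaningless")

    p = fit.predict(cls, m)
    by_class = {
        int(k): float(p[cls == k].mean() * 100.0) for k in np.unique(cls)
    }
    return MSMResult(
        effect_type="CDE" if fit.include_mediator else "TDE",
        coefficients=fit.coefficients(),
        prevalence_overall=float(p.mean() * 100.0),
        prevalence_by_class=by_class,
        mediator_values_used=(
            "observed" if (not fit.include_mediator or mediator_override is None)
            else "overridden"
        ),
    )


@dataclass
class InteractionTest:
    """Wald test of the exposure x mediator product terms."""

    statistic: float
    df: int
    pvalue: float
    include_interaction: bool  # decision at alpha


def test_interaction(
    cohort: pd.DataFrame,
    weights: np.ndarray,
    outcome_col: str = "obese11",
    exposure_col: str = "social_class",
    mediator_col: str = "kcal7",
    alpha: float = 0.05,
) -> InteractionTest:
    """Multiplicative exposure x mediator interaction check.

    Fits the CDE model with product terms and Wald-tests them jointly
    (robust covariance).  The decision (at ``alpha``) governs whether
    downstream models include the interaction.
    """
    fit = fit_msm(
        cohort, weights, outcome_col=outcome_col, exposure_col=exposure_col,
        include_mediator=True, mediator_col=mediator_col,
        include_interaction=True,
    )
    res = fit.results
    k = len(res.params)
    n_int = fit.n_levels - 1
    R = np.zeros((n_int, k))
    for j in range(n_int):
        R[j, k - n_int + j] = 1.0
    wt = res.wald_test(R, scalar=True)
    stat, pval = float(wt.statistic), float(wt.pvalue)
    return InteractionTest(statistic=stat, df=n_int, pvalue=pval,
                           include_interaction=bool(pval < alpha))
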