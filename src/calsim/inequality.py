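"""Relative and absolute inequality in obesity across the class gradient.

The weighted logistic MSM is refitted with social class entered as a single
*continuous* (linear) term; fitted probabilities are standardized at the two
class extremes (class set to 0 = high and 2 = low for every child, other
covariates at their own values) and combined into

* risk ratio   RR = p_low / p_high
* risk difference  RD = (p_low - p_high) x 100   (per 100 children)

so that RD = (RR - 1) * p_high * 100 identically.  Confidence intervals are
nonparametric percentile bootstrap over children, re-deriving the inverse
probability weights inside every resample, because the weight-estimation
step invalidates model-based standard errors.

The bootstrap inner loop re-implements the exact estimation steps
(stratum-frequency exposure model, homoscedastic-Gaussian mediator density
ratio, IRLS weighted logistic) in vectorized numpy for speed; equality with
the statsmodels-based route is covered by the test suite.  The stratified
exposure model is the saturated multinomial MLE — identical to the default
multinomial logit whenever the baseline confounders enter saturated (always
true for the single-confounder default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import class_codes
from .weights import (
    BASELINE_CONFOUNDERS,
    INTERMEDIATE_CONFOUNDERS,
    stabilize_and_trim,
)

__all__ = ["InequalityResult", "estimate_inequalities"]


@dataclass
class InequalityResult:
    """RR / RD between the most and least disadvantaged class, with CIs."""

    risk_ratio: float
    rr_ci: tuple[float, float]
    risk_difference: float  # per 100 children
    rd_ci: tuple[float, float]
    p_high: float
    p_low: float
    n_boot: int
    boot_failures: int
    reference: str = "low (most disadvantaged) vs high (least) social class"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rr": self.risk_ratio, "rr_ci": list(self.rr_ci),
            "rd": self.risk_difference, "rd_ci": list(self.rd_ci),
            "p_high": self.p_high, "p_low": self.p_low,
            "n_boot": self.n_boot, "boot_failures": self.boot_failures,
        }


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Reference-coded indicator columns for levels 1..n_levels-1."""
    return (codes[:, None] == np.arange(1, n_levels)).astype(float)


def _ols_mean_sd(y: np.ndarray, X: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df = len(y) - rank
    if df <= 0:
        raise ZeroDivisionError("no residual degrees of freedom")
    sd = float(np.sqrt(resid @ resid / df))
    if sd <= 0:
        raise ZeroDivisionError("zero residual variance")
    return fitted, sd


def _irls_logistic(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                   tol: float = 1e-10, maxiter: int = 50) -> np.ndarray:
    """Weighted logistic MLE by Newton/IRLS; raises on non-convergence."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        W = w * p * (1 - p)
        g = X.T @ (w * (y - p))
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:  # singular Hessian
            raise RuntimeError("singular Hessian in weighted logistic fit") from e
        beta = beta + step
        eta = np.clip(X @ beta, -30, 30)
        ll = float(w @ (y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-3):
            return beta
        ll_old = ll
    raise RuntimeError("weighted logistic fit did not converge")


class _FastEstimator:
    """Precomputed arrays + per-resample point estimation of RR/RD."""

    def __init__(self, cohort: pd.DataFrame, outcome_col, exposure_col,
                 mediator_col, mediator_override, baseline_confounders,
                 intermediate_confounders, numerator, scale, trim,
                 standardize):
        self.y = cohort[outcome_col].to_numpy(dtype=float)
        self.cls = class_codes(cohort, exposure_col)
        self.n_levels = int(self.cls.max()) + 1
        self.use_mediator = mediator_col is not None
        self.trim = trim
        self.standardize = standardize
        self.numerator = numerator
        self.log_scale = scale == "log"

        # baseline-confounder stratum index (saturated exposure model)
        self.stratum = (
            cohort.groupby(list(baseline_confounders), observed=True)
            .ngroup().to_numpy()
        )
        self.n_strata = int(self.stratum.max()) + 1

        if self.use_mediator:
            m_obs = cohort[mediator_col].to_numpy(dtype=float)
            self.m_density = np.log(m_obs) if scale == "log" else m_obs
            self.m_pred = (
                np.asarray(mediator_override, dtype=float)
                if mediator_override is not None else m_obs
            )
            if len(self.m_pred) != len(cohort):
                raise ValueError("mediator_override length mismatch")
            # density-model designs (shared columns; rows indexed per resample)
            cls_d = _dummies(self.cls, self.n_levels)
            conf_cols = [cls_d]
            for c in (*baseline_confounders, *intermediate_confounders):
                codes = (
                    cohort[c].cat.codes.to_numpy()
                    if isinstance(cohort[c].dtype, pd.CategoricalDtype)
                    else cohort[c].to_numpy(dtype=int)
                )
                conf_cols.append(_dummies(codes, int(codes.max()) + 1))
            ones = np.ones((len(cohort), 1))
            self.X_num = np.hstack([ones, cls_d]) if numerator == "exposure" else ones
            self.X_den = np.hstack([ones] + conf_cols)
        else:
            self.m_pred = None

    def weights(self, idx: np.ndarray) -> np.ndarray:
        cls, stratum = self.cls[idx], self.stratum[idx]
        n = len(idx)
        marg = np.bincount(cls, minlength=self.n_levels) / n
        cell = stratum * self.n_levels + cls
        cell_n = np.bincount(cell, minlength=self.n_strata * self.n_levels)
        strat_n = np.bincount(stratum, minlength=self.n_strata)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = cell_n / np.repeat(strat_n, self.n_levels)
        denom = cond[cell]
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            raise RuntimeError("positivity violated in resample")
        w = marg[cls] / denom

        if self.use_mediator:
            m = self.m_density[idx]
            mu_n, sd_n = _ols_mean_sd(m, self.X_num[idx])
            mu_d, sd_d = _ols_mean_sd(m, self.X_den[idx])
            log_ratio = (
                np.log(sd_d / sd_n)
                - 0.5 * ((m - mu_n) / sd_n) ** 2
                + 0.5 * ((m - mu_d) / sd_d) ** 2
            )
            w = w * np.exp(log_ratio)
        w, _, _, _ = stabilize_and_trim(w, *self.trim)
        return w

    def point(self, idx: np.ndarray) -> tuple[float, float]:
        """(p_high, p_low) standardized from the continuous-class model."""
        w = self.weights(idx)
        y, cls = self.y[idx], self.cls[idx].astype(float)
        cols = [np.ones(len(idx)), cls]
        if self.use_mediator:
            cols.append(self.m_density[idx])
        X = np.column_stack(cols)
        beta = _irls_logistic(X, y, w)

        if self.use_mediator:
            # predictions use the (possibly overridden) mediator on the
            # scale the model was fitted on
            m_pred = self.m_pred[idx]
            m_term = beta[2] * (np.log(m_pred) if self.log_scale else m_pred)
        else:
            m_term = 0.0
        lo_cls, hi_cls = float(self.n_levels - 1), 0.0
        if self.standardize == "cohort":
            p_low = float(np.mean(expit(beta[0] + beta[1] * lo_cls + m_term)))
            p_high = float(np.mean(expit(beta[0] + beta[1] * hi_cls + m_term)))
        elif self.standardize == "within_class":
            mask_lo, mask_hi = cls == lo_cls, cls == hi_cls
            p = expit(beta[0] + beta[1] * cls + m_term)
            p_low, p_high = float(p[mask_lo].mean()), float(p[mask_hi].mean())
        else:
            raise ValueError(f"unknown standardize {self.standardize!r}")
        return p_high, p_low


def estimate_inequalities(
    cohort: pd.DataFrame,
    outcome_col: str = "obese11",
    exposure_col: str = "social_class",
    mediator_col: str | None = "kcal7",
    mediator_override: np.ndarray | None = None,
    baseline_confounders: Sequence[str] = BASELINE_CONFOUNDERS,
    intermediate_confounders: Sequence[str] = INTERMEDIATE_CONFOUNDERS,
    numerator: str = "exposure",
    scale: str = "kcal",
    trim: tuple[float, float] = (1.0, 99.0),
    standardize: str = "cohort",
    n_boot: int = 1000,
    seed: int = 0,
) -> InequalityResult:
    """Risk ratio and risk difference between class extremes, with bootstrap CIs.

    Set ``mediator_col=None`` for the mediator-free (total direct effect)
    contrast; pass ``mediator_override`` to score an intervention scenario
    (predictions use the modified intake, weights remain estimated from the
    observed data).  Point estimates do not depend on ``seed``; only the
    resampling does.  Bootstrap replicates that fail to converge are dropped
    and counted in ``boot_failures``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = _FastEstimator(
        cohort, outcome_col, exposure_col, mediator_col, mediator_override,
        baseline_confounders, intermediate_confounders, numerator, scale,
        trim, standardize,
    )
    n = len(cohort)
    all_idx = np.arange(n)
    p_high, p_low = est.point(all_idx)
    rr = p_low / p_high
    rd = (p_low - p_high) * 100.0

    rng = np.random.default_rng(seed)
    rrs, rds = [], []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ph, pl = est.point(idx)
        except (RuntimeError, ZeroDivisionError):
            failures += 1
            continue
        rrs.append(pl / ph)
        rds.append((pl - ph) * 100.0)
    if len(rrs) < 2:
        raise RuntimeError("bootstrap failed in almost every replicate")
    rr_ci = tuple(float(q) for q in np.percentile(rrs, [2.5, 97.5]))
    rd_ci = tuple(float(q) for q in np.percentile(rds, [2.5, 97.5]))

    return InequalityResult(
        risk_ratio=float(rr), rr_ci=rr_ci,
        risk_difference=float(rd), rd_ci=rd_ci,
        p_high=p_high, p_low=p_low,
        n_boot=n_boot, boot_failures=failures,
        meta={"standardize": standardize, "mediator": mediator_col,
              "scale": scale, "numerator": numerator},
    )
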