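"""Stabilized inverse probability weights for the mediation MSM.

Two weights are combined:

* **weight 1** (exposure weight) balances baseline confounders across social
  class: ``w1 = P(A=a_i) / P(A=a_i | C_i)``, numerator from marginal class
  frequencies, denominator from a multinomial logistic model of class on the
  baseline confounders (or exact stratum frequencies with ``method=
  "saturated"``, identical when the confounders are categorical and the model
  saturated).
* **weight 2** (mediator weight) balances baseline + intermediate confounders
  across the continuous mediator: a stabilized density ratio
  ``f(M_i | A_i) / f(M_i | A_i, C_i, L_i)``, both densities homoscedastic
  Gaussians whose means come from linear models and whose SDs are the
  residual SDs of those models.  ``scale="log"`` models the density of
  ``log M`` instead (the Jacobian cancels in the ratio), which suits the
  right-skew of dietary intake.

The final weight is the product, winsorized ("trimmed") at the 1st/99th
percentile values by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy.stats import norm

from .cohort import class_codes

__all__ = [
    "WeightSet",
    "EstimationError",
    "compute_weight1",
    "compute_weight2",
    "stabilize_and_trim",
    "compute_weight_set",
]

BASELINE_CONFOUNDERS: tuple[str, ...] = ("ethnicity",)
INTERMEDIATE_CONFOUNDERS: tuple[str, ...] = (
    "birthweight_cat",
    "health_cat",
    "activity_cat",
    "tv_cat",
)


class EstimationError(RuntimeError):
    """A weight model could not be estimated (separation, degeneracy...)."""


@dataclass
class WeightSet:
    """Per-child stabilized/trimmed IPWs with diagnostics."""

    w1: np.ndarray
    w2: np.ndarray
    w_final: np.ndarray
    trim_bounds: tuple[float, float]
    n_trimmed_low: int
    n_trimmed_high: int
    meta: dict = field(default_factory=dict)

    def diagnostics(self) -> dict:
        d = {
            "mean_w1": float(self.w1.mean()),
            "mean_w2": float(self.w2.mean()),
            "mean_w_final": float(self.w_final.mean()),
            "min_w_final": float(self.w_final.min()),
            "max_w_final": float(self.w_final.max()),
            "trim_bounds": list(self.trim_bounds),
            "n_trimmed_low": self.n_trimmed_low,
            "n_trimmed_high": self.n_trimmed_high,
        }
        d.update(self.meta)
        return d

    def to_frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "child_id": cohort["child_id"].to_numpy(),
                "w1": self.w1,
                "w2": self.w2,
                "w_final": self.w_final,
            }
        )


def _check_positivity(cohort, exposure_col, confounders):
    """Every exposure level must occur in every confounder stratum."""
    a = cohort[exposure_col]
    n_levels = a.nunique()
    strata = cohort.groupby(list(confounders), observed=True)[exposure_col]
    for key, grp in strata:
        if grp.nunique() < n_levels:
            missing = set(a.unique()) - set(grp.unique())
            raise EstimationError(
                f"exposure level(s) {sorted(map(str, missing))} absent in "
                f"confounder stratum {key!r}: positivity violated"
            )


def compute_weight1(
    cohort: pd.DataFrame,
    exposure_col: str = "social_class",
    baseline_confounders: Sequence[str] = BASELINE_CONFOUNDERS,
    method: str = "multinomial_logit",
) -> np.ndarray:
    """Stabilized exposure weight ``P(A=a_i) / P(A=a_i | C_i)``.

    ``method="multinomial_logit"`` fits class on main effects of the
    confounders; ``"saturated"`` uses exact stratum frequencies (the MLE of
    the fully interacted model).  With a single categorical confounder the
    two coincide.
    """
    raw = class_codes(cohort, exposure_col)
    _, a = np.unique(raw, return_inverse=True)  # dense codes over observed levels
    n = len(a)
    n_levels = int(a.max()) + 1
    marg = np.bincount(a, minlength=n_levels) / n
    numer = marg[a]

    _check_positivity(cohort, exposure_col, baseline_confounders)

    if method == "saturated":
        key = cohort.groupby(list(baseline_confounders), observed=True).ngroup().to_numpy()
        denom = np.empty(n)
        for s in np.unique(key):
            idx = key == s
            freq = np.bincount(a[idx], minlength=n_levels) / idx.sum()
            denom[idx] = freq[a[idx]]
    elif method == "multinomial_logit":
        rhs = " + ".join(f"C({c})" for c in baseline_confounders)
        exog = np.asarray(dmatrix("1 + " + rhs, cohort, return_type="matrix"))
        res = sm.MNLogit(a, exog).fit(method="newton", maxiter=200, tol=1e-10,
                                      disp=False)
        probs = res.predict(exog)
        denom = probs[np.arange(n), a]
    else:
        raise ValueError(f"unknown method {method!r}")

    w = numer / denom
    if not np.all(np.isfinite(w) & (w > 0)):
        raise EstimationError("weight 1 produced non-positive or non-finite values")
    return w


def _gaussian_density_params(y: np.ndarray, exog: np.ndarray):
    """Fitted mean and residual SD of a homoscedastic linear model."""
    res = sm.OLS(y, exog).fit()
    sd = float(np.sqrt(res.mse_resid))
    if not np.isfinite(sd) or sd <= 0:
        raise EstimationError("degenerate mediator model: zero residual variance")
    return res.fittedvalues, sd


def compute_weight2(
    cohort: pd.DataFrame,
    mediator_col: str = "kcal7",
    exposure_col: str = "social_class",
    baseline_confounders: Sequence[str] = BASELINE_CONFOUNDERS,
    intermediate_confounders: Sequence[str] = INTERMEDIATE_CONFOUNDERS,
    numerator: str = "exposure",
    scale: str = "kcal",
) -> np.ndarray:
    """Stabilized mediator density-ratio weight ``f(M|A) / f(M|A,C,L)``.

    ``numerator="exposure"`` conditions the numerator density on the exposure
    (standard stabilization for a controlled-direct-effect weight);
    ``"marginal"`` uses the marginal density of M.  ``scale`` is ``"kcal"``
    (Gaussian on the kcal scale) or ``"log"`` (Gaussian for log-intake).
    """
    m = cohort[mediator_col].to_numpy(dtype=float)
    if scale == "log":
        m = np.log(m)
    elif scale != "kcal":
        raise ValueError(f"unknown scale {scale!r}")

    if numerator == "exposure":
        num_rhs = f"C({exposure_col})"
    elif numerator == "marginal":
        num_rhs = "1"
    else:
        raise ValueError(f"unknown numerator {numerator!r}")
    den_rhs = " + ".join(
        [f"C({exposure_col})"]
        + [f"C({c})" for c in (*baseline_confounders, *intermediate_confounders)]
    )

    mu_num, sd_num = _gaussian_density_params(
        m, np.asarray(dmatrix("1 + " + num_rhs, cohort, return_type="matrix"))
    )
    mu_den, sd_den = _gaussian_density_params(
        m, np.asarray(dmatrix("1 + " + den_rhs, cohort, return_type="matrix"))
    )

    w = norm.pdf(m, mu_num, sd_num) / norm.pdf(m, mu_den, sd_den)
    if not np.all(np.isfinite(w) & (w > 0)):
        raise EstimationError("weight 2 produced non-positive or non-finite values")
    return w


def stabilize_and_trim(
    w: np.ndarray, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> tuple[np.ndarray, tuple[float, float], int, int]:
    """Winsorize weights at empirical percentile values.

    Weights below the ``lower_pct`` percentile are set to that percentile's
    value, symmetrically at the top; rows are never dropped (the analytic n
    is unchanged).  Percentile bounds are order statistics (``lower`` /
    ``higher`` interpolation for the bottom / top cut respectively): both
    bounds are then values present in the capped data, which makes
    winsorization an exact fixed point (idempotent) — an interpolated bound
    would drift on re-application.
    Returns ``(trimmed, (lo, hi), n_capped_low, n_capped_high)``.
    """
    w = np.asarray(w, dtype=float)
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    if np.unique(w).size < 2:
        return w.copy(), (float(w.min(initial=np.nan)), float(w.max(initial=np.nan))), 0, 0
    lo = np.percentile(w, lower_pct, method="lower")
    hi = np.percentile(w, upper_pct, method="higher")
    n_low = int((w < lo).sum())
    n_high = int((w > hi).sum())
    return np.clip(w, lo, hi), (float(lo), float(hi)), n_low, n_high


def compute_weight_set(
    cohort: pd.DataFrame,
    exposure_col: str = "social_class",
    mediator_col: str = "kcal7",
    baseline_confounders: Sequence[str] = BASELINE_CONFOUNDERS,
    intermediate_confounders: Sequence[str] = INTERMEDIATE_CONFOUNDERS,
    trim: tuple[float, float] = (1.0, 99.0),
    trim_target: str = "final",
    numerator: str = "exposure",
    scale: str = "kcal",
    method: str = "multinomial_logit",
) -> WeightSet:
    """Build the full weight set w1, w2 and the trimmed product.

    ``trim_target="final"`` trims the product (default); ``"separate"`` trims
    w1 and w2 individually before multiplying.
    """
    w1 = compute_weight1(cohort, exposure_col, baseline_confounders, method=method)
    w2 = compute_weight2(
        cohort, mediator_col, exposure_col, baseline_confounders,
        intermediate_confounders, numerator=numerator, scale=scale,
    )
    if trim_target == "separate":
        w1t, b1, l1, h1 = stabilize_and_trim(w1, *trim)
        w2t, b2, l2, h2 = stabilize_and_trim(w2, *trim)
        w_final = w1t * w2t
        bounds = (float(w_final.min()), float(w_final.max()))
        n_low, n_high = l1 + l2, h1 + h2
    elif trim_target == "final":
        w_final, bounds, n_low, n_high = stabilize_and_trim(w1 * w2, *trim)
    else:
        raise ValueError(f"unknown trim_target {trim_target!r}")
    return WeightSet(
        w1=w1, w2=w2, w_final=w_final, trim_bounds=bounds,
        n_trimmed_low=n_low, n_trimmed_high=n_high,
        meta={
            "trim_pct": list(trim), "trim_target": trim_target,
            "numerator": numerator, "scale": scale, "method": method,
        },
    )
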