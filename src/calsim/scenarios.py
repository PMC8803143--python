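"""Simulated calorie-reduction intervention scenarios.

Four preset scenarios mirror the modelled policy actions:

1. **universal_to_ear** — universal intervention shifting the population
   intake distribution so the sex-specific median meets the estimated
   average requirement (EAR); 75% uptake.
2. **targeted_low_income** — intensive intervention (-21.3% of daily intake,
   the healthy-weight-loss recommendation scaled to the adult EAR) targeted
   at children of low-income families; 75% uptake.
3. **indicated_prior_obesity** — the same intensive reduction, indicated for
   children living with obesity at age 7; 100% uptake.
4. **truncate_above_ear** — children consuming above their sex-specific EAR
   have intake fixed exactly at the EAR (no noise); 100% uptake.

Shared machinery: eligibility masks, random uptake assignment, per-child
Gaussian noise around the intended reduction (SD = ``noise_cv`` x intended
mean, draws truncated at zero so nobody's intake increases), and a lower
bound at 2 SD below the pooled cohort mean intake — a child already below
the bound is never reduced, and no treated child is pushed below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import EARTable

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "Scenario1Shift",
    "compute_scenario1_shift",
    "eligibility_mask",
    "assign_uptake",
    "apply_scenario",
    "preset_scenarios",
]

ELIGIBILITY_RULES = ("all", "low_income", "obese7", "above_ear")
EFFECTS = ("shift_to_ear_median", "proportional_reduction", "truncate_at_ear")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one calorie-reduction intervention."""

    name: str
    eligibility: str = "all"
    uptake: float = 1.0
    effect: str = "proportional_reduction"
    reduction_fraction: float = 0.213
    noise_cv: float = 0.25
    ear: EARTable = field(default_factory=EARTable)
    seed: int = 0

    def __post_init__(self):
        if self.eligibility not in ELIGIBILITY_RULES:
            raise ValueError(f"unknown eligibility rule {self.eligibility!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if not 0 <= self.uptake <= 1:
            raise ValueError("uptake must be in [0, 1]")
        if not 0 <= self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def replace(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "eligibility": self.eligibility,
            "uptake": self.uptake, "effect": self.effect,
            "reduction_fraction": self.reduction_fraction,
            "noise_cv": self.noise_cv, "ear": dict(self.ear.ear_by_sex),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        d = dict(d)
        if "ear" in d:
            d["ear"] = EARTable(ear_by_sex=dict(d["ear"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ScenarioOutcome:
    """Modified per-child intake plus summary diagnostics."""

    kcal_modified: np.ndarray
    treated: np.ndarray  # bool per child
    eligible: np.ndarray  # bool per child
    prop_leq_ear_by_sex: dict[str, float]  # percent, post-intervention
    lower_bound: float
    summary: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Scenario1Shift:
    """Sex-specific absolute/percent reductions bringing medians to the EAR."""

    reduction_by_sex: dict[str, float]  # kcal/day
    percent_by_sex: dict[str, float]  # % of the sex median
    overall_percent: float  # sex-share-weighted mean percent


def compute_scenario1_shift(
    median_by_sex: Mapping[str, float],
    ear: EARTable | None = None,
    sex_shares: Mapping[str, float] | None = None,
) -> Scenario1Shift:
    """Reductions needed to bring sex-specific median intake to the EAR.

    ``reduction = max(median - EAR, 0)`` per sex (degenerate inputs floor at
    zero); percent reductions are relative to the sex median and combined
    into an overall percent by the cohort's sex shares.
    """
    ear = ear or EARTable()
    sex_shares = dict(sex_shares or {"male": 0.519, "female": 0.481})
    red, pct = {}, {}
    for sex, med in median_by_sex.items():
        red[sex] = max(float(med) - ear[sex], 0.0)
        pct[sex] = 100.0 * red[sex] / float(med)
    total = sum(sex_shares.values())
    overall = sum(sex_shares[s] * pct[s] for s in pct) / total
    return Scenario1Shift(reduction_by_sex=red, percent_by_sex=pct,
                          overall_percent=overall)


def eligibility_mask(cohort: pd.DataFrame, spec: ScenarioSpec) -> np.ndarray:
    """Boolean per-child eligibility under the scenario's targeting rule.

    ``above_ear`` is a strict inequality: a child consuming exactly the EAR
    is not eligible.
    """
    rule = spec.eligibility
    if rule == "all":
        return np.ones(len(cohort), dtype=bool)
    if rule in ("low_income", "obese7"):
        if rule not in cohort.columns:
            raise KeyError(f"targeting column {rule!r} missing from cohort")
        return cohort[rule].to_numpy(dtype=bool)
    # above_ear
    return cohort["kcal7"].to_numpy(dtype=float) > spec.ear.per_child(cohort)


def assign_uptake(mask: np.ndarray, uptake: float, seed: int) -> np.ndarray:
    """Independently treat each eligible child with probability ``uptake``."""
    if not 0 <= uptake <= 1:
        raise ValueError("uptake must be in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if uptake >= 1.0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    return mask & (rng.random(mask.size) < uptake)


def apply_scenario(cohort: pd.DataFrame, spec: ScenarioSpec) -> ScenarioOutcome:
    """Produce the modified per-child intake vector for one scenario.

    Treated children receive a reduction draw (Gaussian around the intended
    reduction, SD = ``noise_cv`` x intended mean, truncated at zero), or are
    set exactly to the EAR under ``truncate_at_ear``.  The pooled lower
    bound (cohort mean - 2 SD of observed intake) then caps reductions:
    children starting below the bound are left unchanged; children starting
    above it are never pushed below it.  Untreated children are unchanged.
    """
    kcal = cohort["kcal7"].to_numpy(dtype=float)
    sex = cohort["sex"].astype(str).to_numpy()
    eligible = eligibility_mask(cohort, spec)
    treated = assign_uptake(eligible, spec.uptake, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)

    candidate = kcal.copy()
    idx = np.flatnonzero(treated)
    if idx.size:
        if spec.effect == "truncate_at_ear":
            candidate[idx] = spec.ear.per_child(cohort)[idx]
        else:
            if spec.effect == "shift_to_ear_median":
                medians = {
                    s: float(np.median(kcal[sex == s])) for s in ("male", "female")
                }
                shift = compute_scenario1_shift(medians, spec.ear)
                mean_red = np.array([shift.reduction_by_sex[s] for s in sex[idx]])
            else:  # proportional_reduction
                mean_red = spec.reduction_fraction * kcal[idx]
            draw = mean_red + spec.noise_cv * mean_red * rng.standard_normal(idx.size)
            candidate[idx] = kcal[idx] - np.maximum(draw, 0.0)

    bound = float(kcal.mean() - 2.0 * kcal.std(ddof=1))
    modified = kcal.copy()
    above = kcal >= bound
    sel = treated & above
    # positivity guard: a degenerate cohort can put the 2-SD bound at or
    # below zero, but intake must stay positive
    modified[sel] = np.maximum(candidate[sel], max(bound, 1e-6))

    prop_leq = {
        s: float(100.0 * (modified[sex == s] <= spec.ear[s]).mean())
        for s in ("male", "female")
        if (sex == s).any()
    }
    red = kcal[treated] - modified[treated]
    return ScenarioOutcome(
        kcal_modified=modified,
        treated=treated,
        eligible=eligible,
        prop_leq_ear_by_sex=prop_leq,
        lower_bound=bound,
        summary={
            "n_eligible": int(eligible.sum()),
            "n_treated": int(treated.sum()),
            "mean_reduction_treated": float(red.mean()) if red.size else 0.0,
            "median_reduction_treated": float(np.median(red)) if red.size else 0.0,
            "spec": spec.to_dict(),
        },
    )


def preset_scenarios(seed: int = 0, ear: EARTable | None = None) -> list[ScenarioSpec]:
    """The four packaged intervention presets (seeds offset per scenario)."""
    ear = ear or EARTable()
    return [
        ScenarioSpec(name="universal_to_ear", eligibility="all", uptake=0.75,
                     effect="shift_to_ear_median", ear=ear, seed=seed),
        ScenarioSpec(name="targeted_low_income", eligibility="low_income",
                     uptake=0.75, effect="proportional_reduction",
                     reduction_fraction=0.213, ear=ear, seed=seed + 1),
        ScenarioSpec(name="indicated_prior_obesity", eligibility="obese7",
                     uptake=1.0, effect="proportional_reduction",
                     reduction_fraction=0.213, ear=ear, seed=seed + 2),
        ScenarioSpec(name="truncate_above_ear", eligibility="above_ear",
                     uptake=1.0, effect="truncate_at_ear", noise_cv=0.0,
                     ear=ear, seed=seed + 3),
    ]
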