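"""End-to-end run: cohort -> weights -> CDE baseline -> scenarios -> report.

`run_pipeline` reproduces the shape of the study's headline results table:
one controlled-direct-effect (CDE) baseline row plus one row per simulated
intervention, each carrying the share of children at or below the EAR by
sex, standardized obesity prevalence overall and by social class (with
percent change vs the CDE), and risk-ratio / risk-difference inequality
metrics with bootstrap CIs.

Every random ingredient (cohort generation, uptake assignment, reduction
noise, bootstrap resampling) derives its seed from the single master seed,
so a run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import EARTable, read_cohort, write_cohort
from .inequality import estimate_inequalities
from .msm import fit_msm, predict_prevalence, test_interaction
from .scenarios import ScenarioSpec, apply_scenario, preset_scenarios
from .synthetic import SyntheticParams, generate_cohort
from .weights import compute_weight_set

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sensitivity_suite"]

CLASS_LABELS = {0: "high", 1: "mid", 2: "low"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort_path: str | None = None  # read a CSV ...
    synthetic: SyntheticParams | None = None  # ... or generate (default)
    exposure_col: str = "social_class"
    outcome_col: str = "obese11"
    mediator_col: str = "kcal7"
    scenarios: Sequence[ScenarioSpec] | None = None  # default: 4 presets
    n_boot: int = 500
    seed: int = 0
    trim: tuple[float, float] = (1.0, 99.0)
    trim_target: str = "final"
    numerator: str = "exposure"
    scale: str = "kcal"
    refit_per_scenario: bool = False
    drop_incomplete: bool = False  # complete-case filter for external CSVs
    out_dir: str | None = None

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = _params_from_dict(raw["synthetic"])
        if raw.get("scenarios"):
            raw["scenarios"] = [ScenarioSpec.from_dict(d) for d in raw["scenarios"]]
        if "trim" in raw:
            raw["trim"] = tuple(raw["trim"])
        return cls(**raw)


def _params_from_dict(d: Mapping) -> SyntheticParams:
    from .synthetic import MediatorModel, OutcomeModel, TargetingModel

    d = dict(d)
    for key, klass in (("mediator", MediatorModel), ("outcome", OutcomeModel),
                       ("targeting", TargetingModel)):
        if key in d and isinstance(d[key], Mapping):
            d[key] = klass(**d[key])
    if "ear" in d and isinstance(d["ear"], Mapping):
        d["ear"] = EARTable(ear_by_sex=dict(d["ear"]))
    for key in ("p_birthweight_by_class", "p_activity_by_class", "p_tv_by_class"):
        if key in d:
            d[key] = tuple(tuple(r) for r in d[key])
    for key in ("p_class", "p_nonwhite_by_class", "p_unwell_by_class",
                "p_low_income_by_class"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticParams(**d)


@dataclass
class PipelineResult:
    """Report table plus all intermediate results of a run."""

    report: pd.DataFrame
    cohort: pd.DataFrame
    weights: object
    cde: object
    interaction: object
    rows: list[dict]
    run_log: dict


def _jsonable(x):
    if isinstance(x, Mapping):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def _prop_leq_ear(cohort: pd.DataFrame, kcal: np.ndarray, ear: EARTable) -> dict:
    sex = cohort["sex"].astype(str).to_numpy()
    return {
        s: float(100.0 * (kcal[sex == s] <= ear[s]).mean())
        for s in ("male", "female") if (sex == s).any()
    }


def _spawn_seeds(master: int, k: int) -> list[int]:
    """Derive k independent child seeds (< 2**31) from the master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(master).generate_state(k)]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; deterministic given ``config.seed``."""
    gen_seed, scen_seed, boot_seed = _spawn_seeds(config.seed, 3)

    # --- cohort -----------------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        if config.drop_incomplete:
            cohort = cohort.dropna().reset_index(drop=True)
    else:
        params = config.synthetic or SyntheticParams()
        params = params.replace(seed=gen_seed)
        cohort = generate_cohort(params)
    ear = (config.synthetic.ear if config.synthetic is not None else EARTable())

    # --- weights ----------------------------------------------------------
    wset = compute_weight_set(
        cohort, exposure_col=config.exposure_col,
        mediator_col=config.mediator_col, trim=config.trim,
        trim_target=config.trim_target, numerator=config.numerator,
        scale=config.scale,
    )

    # --- interaction check & CDE baseline ---------------------------------
    inter = test_interaction(
        cohort, wset.w_final, outcome_col=config.outcome_col,
        exposure_col=config.exposure_col, mediator_col=config.mediator_col,
    )
    cde_fit = fit_msm(
        cohort, wset.w_final, outcome_col=config.outcome_col,
        exposure_col=config.exposure_col, include_mediator=True,
        mediator_col=config.mediator_col,
        include_interaction=inter.include_interaction,
    )
    tde_fit = fit_msm(
        cohort, stabilize_and_trim_w1(wset, config.trim),
        outcome_col=config.outcome_col, exposure_col=config.exposure_col,
        include_mediator=False,
    )
    cde_prev = predict_prevalence(cde_fit, cohort)
    tde_prev = predict_prevalence(tde_fit, cohort)

    kcal_obs = cohort[config.mediator_col].to_numpy(dtype=float)

    def _inequality(override=None, boot_offset=0):
        return estimate_inequalities(
            cohort, outcome_col=config.outcome_col,
            exposure_col=config.exposure_col,
            mediator_col=config.mediator_col, mediator_override=override,
            numerator=config.numerator, scale=config.scale, trim=config.trim,
            n_boot=config.n_boot, seed=boot_seed + boot_offset,
        )

    rows: list[dict] = []
    cde_ineq = _inequality()
    rows.append(_make_row("CDE", cde_prev, cde_ineq,
                          _prop_leq_ear(cohort, kcal_obs, ear), None))

    # --- scenarios --------------------------------------------------------
    specs = (list(config.scenarios) if config.scenarios is not None
             else preset_scenarios(ear=ear))
    specs = [s.replace(seed=scen_seed + i) for i, s in enumerate(specs)]
    outcomes = {}
    for i, spec in enumerate(specs):
        out = apply_scenario(cohort, spec)
        outcomes[spec.name] = out
        if config.refit_per_scenario:
            mod = cohort.copy()
            mod[config.mediator_col] = out.kcal_modified
            fit_i = fit_msm(
                mod, wset.w_final, outcome_col=config.outcome_col,
                exposure_col=config.exposure_col, include_mediator=True,
                mediator_col=config.mediator_col,
                include_interaction=inter.include_interaction,
            )
            prev = predict_prevalence(fit_i, mod)
        else:
            prev = predict_prevalence(cde_fit, cohort,
                                      mediator_override=out.kcal_modified)
        ineq = _inequality(override=out.kcal_modified, boot_offset=i + 1)
        rows.append(_make_row(spec.name, prev, ineq, out.prop_leq_ear_by_sex,
                              cde_prev, scenario_summary=out.summary))

    report = _report_frame(rows)
    run_log = {
        "config": _config_log(config),
        "seeds": {"master": config.seed, "generator": gen_seed,
                  "scenario_base": scen_seed, "bootstrap_base": boot_seed},
        "n": len(cohort),
        "weight_diagnostics": wset.diagnostics(),
        "interaction_test": {
            "statistic": inter.statistic, "df": inter.df,
            "pvalue": inter.pvalue,
            "include_interaction": inter.include_interaction,
        },
        "tde": {
            "prevalence_overall": tde_prev.prevalence_overall,
            "prevalence_by_class": tde_prev.prevalence_by_class,
            "coefficients": dict(tde_prev.coefficients),
        },
        "refit_per_scenario": config.refit_per_scenario,
    }

    result = PipelineResult(report=report, cohort=cohort, weights=wset,
                            cde=cde_prev, interaction=inter, rows=rows,
                            run_log=run_log)
    if config.out_dir is not None:
        _write_artifacts(result, config, outcomes)
    return result


def stabilize_and_trim_w1(wset, trim):
    """Trimmed exposure-only weight for the TDE model."""
    from .weights import stabilize_and_trim

    w, _, _, _ = stabilize_and_trim(wset.w1, *trim)
    return w


def _make_row(name, prev, ineq, prop_leq, cde_prev, scenario_summary=None):
    row = {
        "row": name,
        "prop_leq_ear_male": prop_leq.get("male"),
        "prop_leq_ear_female": prop_leq.get("female"),
        "prevalence_overall": prev.prevalence_overall,
        "prevalence_by_class": dict(prev.prevalence_by_class),
        "rr": ineq.risk_ratio, "rr_ci": list(ineq.rr_ci),
        "rd": ineq.risk_difference, "rd_ci": list(ineq.rd_ci),
        "boot_failures": ineq.boot_failures,
    }
    if cde_prev is None:
        row["change_overall_pct"] = 0.0
        row["change_by_class_pct"] = {k: 0.0 for k in prev.prevalence_by_class}
    else:
        row["change_overall_pct"] = 100.0 * (
            prev.prevalence_overall - cde_prev.prevalence_overall
        ) / cde_prev.prevalence_overall
        row["change_by_class_pct"] = {
            k: 100.0 * (v - cde_prev.prevalence_by_class[k])
            / cde_prev.prevalence_by_class[k]
            for k, v in prev.prevalence_by_class.items()
        }
    if scenario_summary is not None:
        row["scenario"] = scenario_summary
    return row


def _report_frame(rows: list[dict]) -> pd.DataFrame:
    """Flat display table: 1 dp for percentages, 2 dp for RR/RD."""
    recs = []
    for r in rows:
        rec = {
            "row": r["row"],
            "leq_ear_male_pct": round(r["prop_leq_ear_male"], 1),
            "leq_ear_female_pct": round(r["prop_leq_ear_female"], 1),
            "prev_overall_pct": round(r["prevalence_overall"], 1),
            "change_overall_pct": round(r["change_overall_pct"], 1),
        }
        for code, label in CLASS_LABELS.items():
            if code in r["prevalence_by_class"]:
                rec[f"prev_{label}_pct"] = round(r["prevalence_by_class"][code], 1)
                rec[f"change_{label}_pct"] = round(r["change_by_class_pct"][code], 1)
        rec.update(
            rr=round(r["rr"], 2),
            rr_ci_low=round(r["rr_ci"][0], 2), rr_ci_high=round(r["rr_ci"][1], 2),
            rd=round(r["rd"], 2),
            rd_ci_low=round(r["rd_ci"][0], 2), rd_ci_high=round(r["rd_ci"][1], 2),
        )
        recs.append(rec)
    return pd.DataFrame(recs)


def _config_log(config: RunConfig) -> dict:
    d = {
        "cohort_path": config.cohort_path,
        "exposure_col": config.exposure_col,
        "outcome_col": config.outcome_col,
        "mediator_col": config.mediator_col,
        "n_boot": config.n_boot,
        "trim": list(config.trim), "trim_target": config.trim_target,
        "numerator": config.numerator, "scale": config.scale,
        "refit_per_scenario": config.refit_per_scenario,
    }
    if config.synthetic is not None:
        d["synthetic"] = config.synthetic.to_dict()
    if config.scenarios is not None:
        d["scenarios"] = [s.to_dict() for s in config.scenarios]
    return d


def _write_artifacts(result: PipelineResult, config: RunConfig, outcomes):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, out / "cohort.csv")
    result.weights.to_frame(result.cohort).to_csv(out / "weights.csv", index=False)
    for r in result.rows:
        with open(out / f"result_{r['row']}.json", "w") as fh:
            json.dump(_jsonable(r), fh, indent=2)
    result.report.to_csv(out / "report.csv", index=False)
    with open(out / "report.md", "w") as fh:
        fh.write(result.report.to_markdown(index=False))
        fh.write("\n")
    with open(out / "run_log.json", "w") as fh:
        json.dump(_jsonable(result.run_log), fh, indent=2)


def sensitivity_suite(config: RunConfig) -> dict[str, PipelineResult]:
    """Re-run the analysis under the standard sensitivity variations.

    Universal-intervention uptake swept over 30/75/100%; maternal education
    as the alternative exposure; combined overweight/obesity as the
    alternative outcome.  Returns the base run plus one result per
    variation; when ``config.out_dir`` is set, each lands in a subdirectory
    alongside a ``sensitivity_summary.csv``.
    """
    base_out = config.out_dir

    def _sub(name, **kw):
        c = config.replace(out_dir=(f"{base_out}/{name}" if base_out else None), **kw)
        return run_pipeline(c)

    results = {"base": _sub("base")}
    universal = (config.scenarios or preset_scenarios())[0]
    for uptake in (0.30, 0.75, 1.00):
        results[f"uptake_{int(uptake * 100)}"] = _sub(
            f"uptake_{int(uptake * 100)}",
            scenarios=[universal.replace(uptake=uptake)],
        )
    results["education_exposure"] = _sub("education_exposure",
                                         exposure_col="education")
    results["combined_outcome"] = _sub("combined_outcome",
                                       outcome_col="overweight_or_obese11")

    if base_out is not None:
        summary = pd.concat(
            [r.report.assign(run=name) for name, r in results.items()],
            ignore_index=True,
        )
        summary.to_csv(Path(base_out) / "sensitivity_summary.csv", index=False)
    return results
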