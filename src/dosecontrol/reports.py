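"""End-to-end workflows producing JSON-serializable comparison reports.

These functions glue the modules into the package's four studies: dose
design at diagnosis against fixed concentration targets, cohort burden
fitting with PD estimation, therapy adjustment for tumor-burden reduction,
and robustness analysis of an optimized schedule.  The CLI and the example
scripts are thin wrappers around them.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from . import control as ctl
from .emax import (BENCHMARK_PD, ConversionConstant, PDParameters, efficacy,
                   estimate_conversion, estimate_ec50)
from .errors import EstimationError, FitError
from .pk import (PatientRecord, PKCovariateCoefficients, PKParameters,
                 exposure_integral, fraction_time_above, load_pk_constants,
                 pk_from_covariates, sample_profile, standard_schedule,
                 standard_time_average)
from .tumor import (DEFAULT_A1, DEFAULT_P1, LOG10_E, LeukemiaParams,
                    beta_from_death_rate, csc_death_rate, fit_biphasic,
                    slope_standard_errors)
from .units import HOURS_PER_DAY

logger = logging.getLogger(__name__)

#: default tumor/toxicity weight ratios per sex (male, female)
DEFAULT_PHI = {1: 60.0, 0: 75.0}

#: clinical concentration targets (mg/L): floor and optimum
LOWER_BOUND_TARGET = 0.57
OPTIMAL_TARGET = 1.0


def _schedule_metrics(schedule, pk_params, target, grid_minutes=1.0):
    profile = sample_profile(schedule, pk_params, grid_minutes)
    t_in, t_fin = schedule.horizon
    return {
        "times_h": list(schedule.times),
        "doses_mg": list(schedule.doses),
        "total_dose_mg": schedule.total_dose,
        "auc_mg_h_per_L": exposure_integral(schedule, pk_params, t_in, t_fin),
        "cumulative_distance_mg_h_per_L":
            ctl.cost_optimal_target(profile, target, grid_minutes),
        "fraction_time_above_target": fraction_time_above(profile, target),
    }


def optimize_diagnosis_report(patient: PatientRecord,
                              coeffs: PKCovariateCoefficients | None = None,
                              days: float = 14.0,
                              doses_per_day: Sequence[int] = (1, 3),
                              config: ctl.OptimizerConfig = ctl.OptimizerConfig(),
                              seed: int = 0) -> dict:
    """Optimized schedules for the floor (0.57 mg/L) and optimal (1 mg/L)
    targets, with the standard 400 mg/day regimen as comparator."""
    pk_params = pk_from_covariates(patient, coeffs)
    horizon = (0.0, days * HOURS_PER_DAY)
    report = {"patient": patient.id,
              "pk": {"ka_per_h": pk_params.ka, "f": pk_params.f,
                     "clearance_L_per_h": pk_params.clearance,
                     "volume_L": pk_params.volume},
              "horizon_days": days, "seed": seed, "runs": []}
    targets = (("lower_bound", LOWER_BOUND_TARGET),
               ("optimal_target", OPTIMAL_TARGET))
    for cost_kind, target in targets:
        for dpd in doses_per_day:
            n_doses = int(round(days * dpd))
            problem = ctl.ControlProblem(
                horizon=horizon, n_doses=n_doses, cost_kind=cost_kind,
                pk=pk_params, target_conc=target)
            result = ctl.dcrab_optimize(problem, config, seed=seed)
            std = standard_schedule(days, doses_per_day=dpd)
            entry = {
                "cost_kind": cost_kind, "target_mg_per_L": target,
                "doses_per_day": dpd,
                "best_cost": result.best_cost,
                "baseline_cost": result.baseline_cost,
                "cost_trace": list(result.cost_trace),
                "optimized": _schedule_metrics(result.schedule, pk_params,
                                               target, config.grid_minutes),
                "standard": _schedule_metrics(std, pk_params, target,
                                              config.grid_minutes),
            }
            report["runs"].append(entry)
            logger.info("patient %s %s %d/day: cost %.4g -> %.4g",
                        patient.id, cost_kind, dpd, result.baseline_cost,
                        result.best_cost)
    return report


def fit_burden_report(series_map: Mapping, patients: Sequence[PatientRecord],
                      coeffs: PKCovariateCoefficients | None = None,
                      a1: float = DEFAULT_A1, p1: float = DEFAULT_P1,
                      window_days: float = 40.0,
                      excluded: Mapping | None = None) -> dict:
    """Biphasic fit, CSC death rate, cohort K and patient EC50 for a cohort.

    ``series_map`` maps patient id -> BurdenSeries; demographics come from
    ``patients``.  Patients failing any estimation step are listed with the
    reason rather than aborting the cohort.
    """
    if coeffs is None:
        coeffs = load_pk_constants()
    by_id = {p.id: p for p in patients}
    excluded = dict(excluded or {})
    fitted = {}
    for pid, series in series_map.items():
        if pid not in by_id:
            excluded[pid] = "no demographic record"
            continue
        try:
            fit = fit_biphasic(series)
            se1, se2 = slope_standard_errors(series, fit)
            d1 = csc_death_rate(fit.slope2, a1, p1)
        except (FitError, EstimationError, ValueError) as exc:
            excluded[pid] = str(exc)
            continue
        pk_params = pk_from_covariates(by_id[pid], coeffs)
        c_bar = standard_time_average(pk_params, window_days)
        fitted[pid] = {
            "slope1": fit.slope1, "slope2": fit.slope2,
            "intercept1": fit.intercept1, "intercept2": fit.intercept2,
            "breakpoint_day": fit.breakpoint, "r_squared": fit.r_squared,
            "slope2_se": se2, "d1_per_day": d1,
            "d1_se_per_day": se2 / LOG10_E,
            "c_bar_mg_per_L": c_bar,
            "benchmark_efficacy": float(efficacy(c_bar, BENCHMARK_PD)),
        }
    if not fitted:
        raise FitError("no patient could be fitted: "
                       f"{excluded or 'empty cohort'}")
    conv = estimate_conversion(
        [f["d1_per_day"] for f in fitted.values()],
        [f["benchmark_efficacy"] for f in fitted.values()],
        [f["d1_se_per_day"] for f in fitted.values()])
    for pid, f in fitted.items():
        try:
            f["ec50_mg_per_L"] = estimate_ec50(f["c_bar_mg_per_L"], conv,
                                               f["d1_per_day"])
        except EstimationError as exc:
            f["ec50_mg_per_L"] = None
            f["ec50_error"] = str(exc)
    return {"conversion_k_per_day": conv.k, "conversion_k_ci": conv.k_ci,
            "a1": a1, "p1_per_day": p1, "window_days": window_days,
            "patients": fitted, "excluded": excluded}


def optimize_adjust_report(fit_report: dict,
                           patients: Sequence[PatientRecord],
                           coeffs: PKCovariateCoefficients | None = None,
                           days: float = 14.0,
                           doses_per_day: Sequence[int] = (1,),
                           phi: Mapping | float | None = None,
                           config: ctl.OptimizerConfig = ctl.OptimizerConfig(),
                           seed: int = 0) -> dict:
    """Burden-minimization optimization per fitted patient.

    For each patient the cost trades the predicted CSC log-slope against
    exposure with weight ratio phi (per-sex defaults).  The report compares
    the predicted CSC decay rate under the optimized and standard regimens;
    their ratio is the decay speed-up.
    """
    if coeffs is None:
        coeffs = load_pk_constants()
    by_id = {p.id: p for p in patients}
    conv = ConversionConstant(k=fit_report["conversion_k_per_day"],
                              k_ci=fit_report.get("conversion_k_ci", 0.0))
    a1 = fit_report.get("a1", DEFAULT_A1)
    p1 = fit_report.get("p1_per_day", DEFAULT_P1)
    horizon = (0.0, days * HOURS_PER_DAY)
    out = {"phi": {}, "seed": seed, "patients": {}}
    for pid, fit in fit_report["patients"].items():
        if fit.get("ec50_mg_per_L") is None:
            continue
        patient = by_id[pid]
        if phi is None:
            phi_val = DEFAULT_PHI[patient.sex]
        elif isinstance(phi, Mapping):
            phi_val = phi[patient.sex]
        else:
            phi_val = float(phi)
        if phi_val <= 0:
            raise ValueError("phi must be positive: both the burden and the "
                             "exposure terms must carry weight")
        out["phi"][pid] = phi_val
        pk_params = pk_from_covariates(patient, coeffs)
        pd_params = PDParameters(emax=1.0, ec50=fit["ec50_mg_per_L"], n=1.0)
        leukemia = LeukemiaParams(a1=a1, p1=p1, d1=fit["d1_per_day"])
        entry = {"runs": []}
        for dpd in doses_per_day:
            problem = ctl.ControlProblem(
                horizon=horizon, n_doses=int(round(days * dpd)),
                cost_kind="burden_auc", pk=pk_params, w1=phi_val, w2=1.0,
                pd=pd_params, leukemia=leukemia, conversion=conv)
            result = ctl.dcrab_optimize(problem, config, seed=seed)
            std = standard_schedule(days, doses_per_day=dpd)
            run = {"doses_per_day": dpd, "best_cost": result.best_cost,
                   "cost_trace": list(result.cost_trace)}
            for label, sched in (("optimized", result.schedule),
                                 ("standard", std)):
                c_bar = exposure_integral(sched, pk_params, *horizon) / (
                    horizon[1] - horizon[0])
                lam = (2 * a1 - 1) * p1 - conv.k * float(
                    efficacy(c_bar, pd_params))
                run[label] = {
                    "doses_mg": list(sched.doses),
                    "auc_mg_h_per_L": exposure_integral(sched, pk_params,
                                                        *horizon),
                    "mean_conc_mg_per_L": c_bar,
                    "predicted_csc_lambda_per_day": lam,
                    "predicted_log10_slope_per_day": LOG10_E * lam,
                }
            lam_o = run["optimized"]["predicted_csc_lambda_per_day"]
            lam_s = run["standard"]["predicted_csc_lambda_per_day"]
            run["decay_speedup"] = (lam_o / lam_s
                                    if lam_o < 0 and lam_s < 0 else None)
            entry["runs"].append(run)
        out["patients"][pid] = entry
    return out
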