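"""Open-loop optimal-control engine for discrete dose scheduling.

The control variable is a dose-rate function D(t) (mg/h).  Starting from the
standard regimen expressed as a constant reference rate D0(t), the optimizer
searches for a correction g(t) expanded in a randomized truncated Fourier
basis (the chopped-random-basis family):

    D(t) = max(0, D0(t) + Gamma(t) * sum_k [A_k sin(w_k t) + B_k cos(w_k t)])

with w_k = 2*pi*(k + r_k)/T, r_k ~ U[-0.5, 0.5], and Gamma(t) a fixed
envelope vanishing at both ends of the horizon so initial/final values are
untouched.  Each frequency is optimized in its own "super-iteration" by a
Nelder-Mead direct search over (A_k, B_k) with earlier frequencies frozen at
their optima; every candidate is scored through the full pipeline
discretize -> closed-form concentration -> cost, i.e. the integer-mg
schedule that would actually be prescribed is what is evaluated.

Three cost functionals are provided:

* ``optimal_target``: integral of |C(t) - C_tg| (hit a target concentration,
  no preference for above vs below);
* ``lower_bound``: a step distance — |C - C_tg| where C >= C_tg, a flat
  penalty G where C < C_tg (stay strictly above a floor);
* ``burden_auc``: W1 * log10(e) * net-CSC-growth-rate(C) + W2 * C integrated
  over the horizon in days (shrink the tumor while limiting exposure);
  the ratio phi = W1/W2 sets the aggressiveness of the regimen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from . import pk as pkmod
from .emax import ConversionConstant, PDParameters, efficacy
from .errors import OptimizationError
from .pk import (ConcentrationProfile, DoseSchedule, PKParameters,
                 concentration, exposure_integral, sample_profile)
from .tumor import LOG10_E, LeukemiaParams
from .units import HOURS_PER_DAY

COST_KINDS = ("optimal_target", "lower_bound", "burden_auc")


# ---------------------------------------------------------------------------
# configuration / problem types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizerConfig:
    """Tunables of the direct-search optimizer.

    ``amplitude_scale_fraction`` sets the initial Nelder-Mead simplex edge as
    a fraction of the reference dose rate.  ``gamma_shape`` selects the
    boundary envelope: ``trapezoid`` (flat top, cosine ramps over
    ``gamma_ramp_fraction`` of the horizon at each end — the default, so the
    correction keeps authority near therapy start) or ``half_sine``.
    """

    n_frequencies: int = 8
    evals_per_superiteration: int = 200
    dose_max_daily_mg: float = 800.0
    rounding_grain_mg: float = 1.0
    grid_minutes: float = 1.0
    gamma_shape: str = "trapezoid"
    gamma_ramp_fraction: float = 0.05
    amplitude_scale_fraction: float = 0.10
    optimize_times: bool = False

    def __post_init__(self):
        if self.gamma_shape not in ("trapezoid", "half_sine"):
            raise ValueError("gamma_shape must be 'trapezoid' or 'half_sine'")
        if self.n_frequencies < 1 or self.evals_per_superiteration < 1:
            raise ValueError("budgets must be positive")


@dataclass(frozen=True)
class ControlProblem:
    """A dose-design task: horizon, dose count, cost functional, models."""

    horizon: tuple
    n_doses: int
    cost_kind: str
    pk: PKParameters
    target_conc: float = 0.0
    penalty_g: Optional[float] = None
    w1: float = 0.0
    w2: float = 0.0
    dose_max: Optional[float] = None
    pd: Optional[PDParameters] = None
    leukemia: Optional[LeukemiaParams] = None
    conversion: Optional[ConversionConstant] = None

    def __post_init__(self):
        t_in, t_fin = self.horizon
        if not t_in < t_fin:
            raise ValueError("horizon must satisfy t_in < t_fin")
        if self.n_doses < 1:
            raise ValueError("need at least one dose")
        if self.cost_kind not in COST_KINDS:
            raise ValueError(f"cost_kind must be one of {COST_KINDS}")
        if self.cost_kind in ("optimal_target", "lower_bound"):
            if not self.target_conc > 0:
                raise ValueError("target cost kinds require target_conc > 0")
        if self.cost_kind == "burden_auc":
            if self.pd is None or self.leukemia is None or self.conversion is None:
                raise ValueError("burden_auc requires pd, leukemia and "
                                 "conversion models")
            if self.w1 < 0 or self.w2 < 0 or (self.w1 == 0 and self.w2 == 0):
                raise ValueError("weights must be non-negative, not both zero")

    @property
    def step_penalty(self) -> float:
        """Penalty constant G; default 10x the target concentration."""
        if self.penalty_g is not None:
            return self.penalty_g
        return 10.0 * self.target_conc

    def per_dose_cap(self, config: OptimizerConfig) -> float:
        """Per-dose cap in mg (daily ceiling scaled to the dose interval)."""
        if self.dose_max is not None:
            return self.dose_max
        t_in, t_fin = self.horizon
        interval = (t_fin - t_in) / self.n_doses
        return config.dose_max_daily_mg * interval / HOURS_PER_DAY


@dataclass(frozen=True)
class FourierCorrection:
    """Randomized truncated Fourier correction with boundary envelope."""

    amplitudes: tuple          # ((A_k, B_k), ...)
    r_values: tuple            # random frequency offsets r_k in [-0.5, 0.5]
    horizon: tuple
    gamma_shape: str = "trapezoid"
    gamma_ramp_fraction: float = 0.05

    def __post_init__(self):
        if len(self.amplitudes) != len(self.r_values):
            raise ValueError("one (A, B) pair per frequency required")

    @property
    def n_c(self) -> int:
        return len(self.amplitudes)

    def frequencies(self) -> np.ndarray:
        """Angular frequencies w_k = 2*pi*(k + r_k)/T, k = 1..n_c (1/h)."""
        t_in, t_fin = self.horizon
        T = t_fin - t_in
        k = np.arange(1, self.n_c + 1, dtype=float)
        return 2.0 * np.pi * (k + np.asarray(self.r_values)) / T

    def envelope(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t_in, t_fin = self.horizon
        T = t_fin - t_in
        x = np.clip((t - t_in) / T, 0.0, 1.0)
        if self.gamma_shape == "half_sine":
            return np.sin(np.pi * x)
        r = self.gamma_ramp_fraction
        up = 0.5 * (1.0 - np.cos(np.pi * x / r))
        down = 0.5 * (1.0 - np.cos(np.pi * (1.0 - x) / r))
        return np.where(x < r, up, np.where(x > 1.0 - r, down, 1.0))

    def __call__(self, t):
        """Correction g(t) in mg/h (vanishes at the horizon boundaries)."""
        t = np.asarray(t, dtype=float)
        t_in, _ = self.horizon
        w = self.frequencies()
        ab = np.asarray(self.amplitudes, dtype=float)
        if ab.size == 0:
            return np.zeros_like(t)
        phase = np.multiply.outer(t - t_in, w)
        series = np.sin(phase) @ ab[:, 0] + np.cos(phase) @ ab[:, 1]
        return self.envelope(t) * series


@dataclass(frozen=True)
class OptimizationResult:
    """Optimized schedule plus the search trace needed to reproduce it."""

    schedule: DoseSchedule
    raw_doses: tuple           # pre-rounding dose masses (mg)
    best_cost: float
    cost_trace: tuple          # best cost after each super-iteration
    seed: int
    n_super_iterations: int
    correction: FourierCorrection
    baseline_cost: float


# ---------------------------------------------------------------------------
# dose function machinery
# ---------------------------------------------------------------------------

def constant_rate(daily_dose_mg: float = pkmod.STANDARD_DAILY_DOSE_MG) -> Callable:
    """Reference dose-rate function: the standard daily dose spread uniformly
    (mg/h), so integrating over any day recovers the standard daily dose."""
    rate = daily_dose_mg / HOURS_PER_DAY

    def d0(t):
        return np.full_like(np.asarray(t, dtype=float), rate)

    return d0


def build_dose_function(reference: Callable,
                        correction: FourierCorrection) -> Callable:
    """D(t) = max(0, D0(t) + g(t)) — negative rates are clamped to zero."""

    def d_fn(t):
        t = np.asarray(t, dtype=float)
        return np.maximum(0.0, reference(t) + correction(t))

    return d_fn


# Gauss-Legendre panel rule used for all dose-mass integrals.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


def integrate_rate(d_fn: Callable, a: float, b: float,
                   max_panel_hours: float = 6.0) -> float:
    """Integral of a dose-rate function over [a, b] (mg), composite
    Gauss-Legendre with panels no wider than ``max_panel_hours``."""
    n_panels = max(1, int(math.ceil((b - a) / max_panel_hours)))
    edges = np.linspace(a, b, n_panels + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    pts = mids[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = d_fn(pts.ravel()).reshape(pts.shape)
    return float(np.sum(vals @ _GL_WEIGHTS * half))


def dose_times(n_doses: int, horizon: tuple) -> np.ndarray:
    """Uniform administration times t_i = t_in + i*T/n_doses, i = 0..n-1."""
    t_in, t_fin = horizon
    return t_in + (t_fin - t_in) * np.arange(n_doses) / n_doses


def discretize_doses(d_fn: Callable, n_doses: int, horizon: tuple,
                     dose_max: float = np.inf,
                     rounding_grain_mg: float = 1.0):
    """Map a dose-rate function to a discrete schedule.

    Doses sit at uniform times; each dose mass is the integral of D(t) over
    the interval it opens, then rounded to the grain and clamped to
    [0, dose_max].  Returns ``(schedule, raw_doses)`` where ``raw_doses``
    are the exact pre-rounding interval integrals (mass conservation:
    their sum equals the integral of D over the whole horizon).
    """
    times = dose_times(n_doses, horizon)
    edges = np.append(times, horizon[1])
    raw = np.array([integrate_rate(d_fn, a, b)
                    for a, b in zip(edges[:-1], edges[1:])])
    rounded = np.round(raw / rounding_grain_mg) * rounding_grain_mg
    clamped = np.clip(rounded, 0.0, dose_max)
    sched = DoseSchedule(times=tuple(times), doses=tuple(clamped),
                         horizon=horizon)
    return sched, tuple(raw)


# ---------------------------------------------------------------------------
# cost functionals
# ---------------------------------------------------------------------------

def _threshold_segments(schedule: DoseSchedule, pk: PKParameters,
                        threshold: float, grid_minutes: float = 1.0):
    """Partition the horizon into segments of constant sign of C - threshold.

    Crossings are located by inverse linear interpolation on a fine grid of
    the closed form (the profile varies over hours, so sub-grid double
    crossings do not occur in practice).  Yields (a, b, above) triples.
    """
    t_in, t_fin = schedule.horizon
    n = int(round((t_fin - t_in) * 60.0 / grid_minutes)) + 1
    grid = np.linspace(t_in, t_fin, n)
    diff = concentration(grid, schedule, pk) - threshold
    above = diff >= 0
    change = np.nonzero(above[1:] != above[:-1])[0]
    cuts = [t_in]
    for i in change:
        d0, d1 = diff[i], diff[i + 1]
        frac = d0 / (d0 - d1) if d0 != d1 else 0.5
        cuts.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    cuts.append(t_fin)
    segs = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        mid_idx = np.searchsorted(grid, 0.5 * (a + b))
        segs.append((a, b, bool(above[min(mid_idx, n - 1)])))
    return segs


def cost_optimal_target(profile: ConcentrationProfile, c_tg: float,
                        grid_minutes: float = 1.0) -> float:
    """Integral of |C(t) - C_tg| over the horizon (mg*h/L).

    Exact on each constant-sign segment via the analytic exposure integral.
    """
    sched, pk = profile.schedule, profile.pk
    total = 0.0
    for a, b, above in _threshold_segments(sched, pk, c_tg, grid_minutes):
        seg = exposure_integral(sched, pk, a, b) - c_tg * (b - a)
        total += seg if above else -seg
    return float(total)


def cost_lower_bound(profile: ConcentrationProfile, c_tg: float,
                     g_penalty: float, grid_minutes: float = 1.0) -> float:
    """Step-distance cost: |C - C_tg| above the floor, flat G below it."""
    if not g_penalty > 0:
        raise ValueError("step penalty G must be positive")
    sched, pk = profile.schedule, profile.pk
    total = 0.0
    for a, b, above in _threshold_segments(sched, pk, c_tg, grid_minutes):
        if above:
            total += exposure_integral(sched, pk, a, b) - c_tg * (b - a)
        else:
            total += g_penalty * (b - a)
    return float(total)


def cost_burden_auc(profile: ConcentrationProfile, pd: PDParameters,
                    leukemia: LeukemiaParams, conversion: ConversionConstant,
                    w1: float, w2: float) -> float:
    """Tumor-plus-exposure cost, integrated over the horizon in *days*:

        int dt_days [ W1*log10(e)*((2a1-1)p1 - K*E(C(t))) + W2*C(t) ]

    The first term is the instantaneous log10-slope of the CSC compartment
    under concentration C (negative when the drug is winning); the second is
    the exposure (AUC) penalty.  Composite Gauss-Legendre between dose times
    (the integrand is smooth away from them).
    """
    if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
        raise ValueError("weights must be non-negative, not both zero")
    sched, pk = profile.schedule, profile.pk
    t_in, t_fin = sched.horizon
    lam0 = (2 * leukemia.a1 - 1) * leukemia.p1  # untreated growth, 1/day
    edges = np.unique(np.concatenate(
        [[t_in, t_fin], [t for t in sched.times if t_in < t < t_fin]]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    pts = (mids[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    c = concentration(pts, sched, pk)
    integrand = (w1 * LOG10_E * (lam0 - conversion.k * efficacy(c, pd))
                 + w2 * c).reshape(len(mids), -1)
    hours = float(np.sum(integrand @ _GL_WEIGHTS * half))
    return hours / HOURS_PER_DAY


def evaluate_cost(schedule: DoseSchedule, problem: ControlProblem,
                  grid_minutes: float = 1.0) -> float:
    """Score a discrete schedule under the problem's cost functional."""
    profile = ConcentrationProfile(
        grid=np.asarray(schedule.horizon),
        values=np.zeros(2), schedule=schedule, pk=problem.pk)
    if problem.cost_kind == "optimal_target":
        return cost_optimal_target(profile, problem.target_conc, grid_minutes)
    if problem.cost_kind == "lower_bound":
        return cost_lower_bound(profile, problem.target_conc,
                                problem.step_penalty, grid_minutes)
    return cost_burden_auc(profile, problem.pd, problem.leukemia,
                           problem.conversion, problem.w1, problem.w2)


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def dcrab_optimize(problem: ControlProblem,
                   config: OptimizerConfig = OptimizerConfig(),
                   seed: int = 0,
                   reference: Callable | None = None) -> OptimizationResult:
    """Chopped-random-basis dose optimization with super-iterations.

    One randomized Fourier frequency is opened per super-iteration and its
    (A_k, B_k) pair optimized by Nelder-Mead with all earlier pairs frozen;
    a candidate is accepted only if it improves the best cost, so the trace
    is non-increasing by construction.  Deterministic given (problem,
    config, seed).
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = constant_rate()
    horizon = tuple(problem.horizon)
    cap = problem.per_dose_cap(config)
    r_values = tuple(rng.uniform(-0.5, 0.5, size=config.n_frequencies))
    amplitudes = [(0.0, 0.0)] * config.n_frequencies

    def make_correction(k: int, a: float, b: float) -> FourierCorrection:
        amps = list(amplitudes)
        if k is not None:
            amps[k] = (a, b)
        return FourierCorrection(
            amplitudes=tuple(amps), r_values=r_values, horizon=horizon,
            gamma_shape=config.gamma_shape,
            gamma_ramp_fraction=config.gamma_ramp_fraction)

    def score(corr: FourierCorrection):
        d_fn = build_dose_function(reference, corr)
        sched, raw = discretize_doses(d_fn, problem.n_doses, horizon,
                                      dose_max=cap,
                                      rounding_grain_mg=config.rounding_grain_mg)
        cost = evaluate_cost(sched, problem, config.grid_minutes)
        if not np.isfinite(cost):
            raise OptimizationError(
                f"non-finite cost {cost} for amplitudes {corr.amplitudes}")
        return cost, sched, raw

    best_cost, best_sched, best_raw = score(make_correction(None, 0.0, 0.0))
    baseline_cost = best_cost
    trace = [best_cost]
    scale = config.amplitude_scale_fraction * float(
        np.mean(reference(np.asarray(horizon))))

    for k in range(config.n_frequencies):
        local_best = {"cost": np.inf, "ab": (0.0, 0.0),
                      "sched": None, "raw": None}

        def objective(x):
            cost, sched, raw = score(make_correction(k, x[0], x[1]))
            if cost < local_best["cost"]:
                local_best.update(cost=cost, ab=(float(x[0]), float(x[1])),
                                  sched=sched, raw=raw)
            return cost

        x0 = np.zeros(2)
        simplex = np.array([[0.0, 0.0], [scale, 0.0], [0.0, scale]])
        minimize(objective, x0, method="Nelder-Mead",
                 options={"maxfev": config.evals_per_superiteration,
                          "initial_simplex": simplex,
                          "xatol": 1e-3, "fatol": 1e-6})
        if local_best["cost"] < best_cost:
            best_cost = local_best["cost"]
            best_sched = local_best["sched"]
            best_raw = local_best["raw"]
            amplitudes[k] = local_best["ab"]
        trace.append(best_cost)

    if config.optimize_times:
        best_cost, best_sched, trace = _refine_dose_times(
            problem, config, best_sched, best_cost, trace)

    return OptimizationResult(
        schedule=best_sched, raw_doses=tuple(best_raw), best_cost=best_cost,
        cost_trace=tuple(trace), seed=seed,
        n_super_iterations=config.n_frequencies,
        correction=make_correction(None, 0.0, 0.0),
        baseline_cost=baseline_cost)


def _refine_dose_times(problem, config, schedule, best_cost, trace):
    """Optional extra stage: direct search over per-dose time offsets.

    Offsets are clipped so times stay sorted, strictly increasing and
    inside the horizon; the first dose stays at the horizon start.  A
    refined schedule is accepted only if it improves the cost.
    """
    t_in, t_fin = problem.horizon
    base_times = np.asarray(schedule.times)
    n = len(base_times)
    if n < 2:
        return best_cost, schedule, trace
    min_gap = 1e-3 * (t_fin - t_in)

    def make_schedule(offsets):
        times = base_times + np.concatenate([[0.0], offsets])  # t_0 fixed
        times = np.clip(times, t_in, t_fin - min_gap)
        times = np.maximum.accumulate(times + min_gap * np.arange(n) * 1e-6)
        if np.any(np.diff(times) <= 0):
            return None
        return DoseSchedule(times=tuple(times), doses=schedule.doses,
                            horizon=problem.horizon)

    state = {"cost": best_cost, "sched": schedule}

    def objective(offsets):
        cand = make_schedule(offsets)
        if cand is None:
            return state["cost"] * 10 + 1.0
        cost = evaluate_cost(cand, problem, config.grid_minutes)
        if cost < state["cost"]:
            state.update(cost=cost, sched=cand)
        return cost

    x0 = np.zeros(n - 1)
    spread = 0.05 * (t_fin - t_in) / n
    simplex = np.vstack([x0] + [x0 + spread * np.eye(n - 1)[i]
                                for i in range(n - 1)])
    minimize(objective, x0, method="Nelder-Mead",
             options={"maxfev": config.evals_per_superiteration,
                      "initial_simplex": simplex, "fatol": 1e-6})
    return state["cost"], state["sched"], tuple(trace) + (state["cost"],)


# ---------------------------------------------------------------------------
# phi scan
# ---------------------------------------------------------------------------

def phi_scan(patients: Sequence[tuple], leukemia: LeukemiaParams,
             conversion: ConversionConstant, phi_values: Sequence[float],
             horizon_days: float = 14.0, doses_per_day: int = 1,
             config: OptimizerConfig = OptimizerConfig(), seed: int = 0):
    """Scan the tumor/toxicity weight ratio phi = W1/W2 across a cohort.

    ``patients`` is a sequence of (patient_id, PKParameters, PDParameters).
    Returns a pandas DataFrame with one row per (patient, phi): the 14-day
    AUC of the optimized schedule, the time-average concentration, and the
    efficacy at that average — the sensitivity table behind weight choice.
    """
    import pandas as pd_df

    if len(phi_values) == 0:
        raise ValueError("need at least one phi value")
    horizon = (0.0, horizon_days * HOURS_PER_DAY)
    n_doses = int(round(horizon_days * doses_per_day))
    rows = []
    for pid, pk_params, pd_params in patients:
        for phi in phi_values:
            problem = ControlProblem(
                horizon=horizon, n_doses=n_doses, cost_kind="burden_auc",
                pk=pk_params, w1=float(phi), w2=1.0, pd=pd_params,
                leukemia=leukemia, conversion=conversion)
            res = dcrab_optimize(problem, config, seed=seed)
            total_auc = exposure_integral(res.schedule, pk_params,
                                          horizon[0], horizon[1])
            c_bar = total_auc / (horizon[1] - horizon[0])
            rows.append({"patient": pid, "phi": float(phi),
                         "auc_mg_h_per_L": total_auc, "mean_conc_mg_per_L": c_bar,
                         "efficacy_at_mean": float(efficacy(c_bar, pd_params)),
                         "best_cost": res.best_cost})
    return pd_df.DataFrame(rows)
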