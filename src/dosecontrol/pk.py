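"""Patient-specific one-compartment oral-absorption pharmacokinetics.

The forward model is the classic Bateman problem: a first-order
gastro-intestinal depot feeding a single well-mixed blood compartment with
linear elimination,

    d chi_g / dt = -ka * chi_g,          chi_g(0) = f * D
    d chi_b / dt = +ka * chi_g - CL * C, C = chi_b / v

whose single-dose solution is the two-exponential Bateman curve.  Multi-dose
profiles follow by superposition (the system is linear), so the closed form
is exact and cheap enough to sit inside an optimization loop; a numerical ODE
integrator is used only as an independent oracle in the test suite.

Patient covariates (age, sex, body weight) enter through the clearance and
the volume of distribution:

    CL = theta_a + theta_1*(BW - BW_mean)/BW_mean + theta_2*q - theta_2*(1-q)
         + theta_3*(AGE - AGE_mean)/AGE_mean
    v  = theta_b + theta_4*q - theta_4*(1-q)

with q = 1 for males, q = 0 for females.  The numeric coefficients ship in a
versioned JSON data file and can be overridden at run time.

Units: hours and mg/L throughout this module; day-denominated inputs are
converted at the boundary (see :mod:`dosecontrol.units`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidCovariatesError
from .units import HOURS_PER_DAY

logger = logging.getLogger(__name__)

#: relative ka/ke gap below which the degenerate (ka == ke) limit form is used
_DEGENERATE_RTOL = 1e-10

STANDARD_DAILY_DOSE_MG = 400.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """Demographics driving the covariate PK model.

    ``sex`` is the binary covariate q: 1 for male, 0 for female.
    """

    id: str
    age: float
    sex: int
    body_weight: float

    def __post_init__(self):
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be positive, got {self.body_weight}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex}")


@dataclass(frozen=True)
class PKCovariateCoefficients:
    """Population coefficients of the covariate clearance/volume model."""

    theta_a: float
    theta_b: float
    theta_1: float
    theta_2: float
    theta_3: float
    theta_4: float
    bw_mean: float
    age_mean: float
    ka: float
    f: float

    def __post_init__(self):
        if not self.ka > 0:
            raise ValueError("ka must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("bioavailability f must be in (0, 1]")
        if not (self.bw_mean > 0 and self.age_mean > 0):
            raise ValueError("population means must be positive")


@dataclass(frozen=True)
class PKParameters:
    """Individual PK parameters: absorption, bioavailability, CL, volume."""

    ka: float
    f: float
    clearance: float
    volume: float

    def __post_init__(self):
        if not (self.clearance > 0 and self.volume > 0 and self.ka > 0):
            raise ValueError("ka, clearance and volume must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("bioavailability f must be in (0, 1]")

    @property
    def ke(self) -> float:
        """Elimination rate CL/v in 1/h."""
        return self.clearance / self.volume


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered (time, dose) pairs over a therapy horizon, hours / mg."""

    times: tuple
    doses: tuple
    horizon: tuple

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        doses = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "times", tuple(times))
        object.__setattr__(self, "doses", tuple(doses))
        if len(times) != len(doses):
            raise ValueError("times and doses must have equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("dose times must be strictly increasing")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        t_in, t_fin = self.horizon
        if not t_in < t_fin:
            raise ValueError("horizon must satisfy t_in < t_fin")
        if len(times) and (times[0] < t_in or times[-1] > t_fin):
            raise ValueError("dose times must lie inside the horizon")

    @property
    def total_dose(self) -> float:
        return float(np.sum(self.doses))


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration sampled on a grid, with its generating schedule/PK."""

    grid: np.ndarray
    values: np.ndarray
    schedule: DoseSchedule
    pk: PKParameters

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.shape != values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(values < -1e-12):
            raise ValueError("concentrations must be non-negative")


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------

def load_pk_constants(path=None) -> PKCovariateCoefficients:
    """Load covariate coefficients from JSON (bundled defaults if no path)."""
    if path is None:
        text = resources.files("dosecontrol.data").joinpath(
            "pk_constants.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    keys = ("theta_a", "theta_b", "theta_1", "theta_2", "theta_3", "theta_4",
            "bw_mean", "age_mean", "ka", "f")
    return PKCovariateCoefficients(**{k: float(raw[k]) for k in keys})


def clearance_from_covariates(patient: PatientRecord,
                              coeffs: PKCovariateCoefficients) -> float:
    """Clearance in L/h from age, sex and body weight."""
    q = patient.sex
    cl = (coeffs.theta_a
          + coeffs.theta_1 * (patient.body_weight - coeffs.bw_mean) / coeffs.bw_mean
          + coeffs.theta_2 * q - coeffs.theta_2 * (1 - q)
          + coeffs.theta_3 * (patient.age - coeffs.age_mean) / coeffs.age_mean)
    if cl <= 0:
        raise InvalidCovariatesError(
            f"non-positive clearance {cl:.3g} L/h for patient {patient.id!r} "
            f"(age={patient.age}, sex={patient.sex}, bw={patient.body_weight})")
    return float(cl)


def volume_from_covariates(patient: PatientRecord,
                           coeffs: PKCovariateCoefficients) -> float:
    """Volume of distribution in L from sex."""
    q = patient.sex
    v = coeffs.theta_b + coeffs.theta_4 * q - coeffs.theta_4 * (1 - q)
    if v <= 0:
        raise InvalidCovariatesError(
            f"non-positive volume {v:.3g} L for patient {patient.id!r} "
            f"(sex={patient.sex})")
    return float(v)


def pk_from_covariates(patient: PatientRecord,
                       coeffs: PKCovariateCoefficients | None = None) -> PKParameters:
    """Build the individual PK parameter set for one patient."""
    if coeffs is None:
        coeffs = load_pk_constants()
    return PKParameters(
        ka=coeffs.ka,
        f=coeffs.f,
        clearance=clearance_from_covariates(patient, coeffs),
        volume=volume_from_covariates(patient, coeffs),
    )


def reference_patient(sex: int = 1,
                      coeffs: PKCovariateCoefficients | None = None,
                      patient_id: str = "average") -> PatientRecord:
    """The population-average patient of the given sex (age and BW at the
    population means of the covariate model)."""
    if coeffs is None:
        coeffs = load_pk_constants()
    return PatientRecord(id=patient_id, age=coeffs.age_mean, sex=sex,
                         body_weight=coeffs.bw_mean)


_BW_TABLE = None


def _bw_table():
    global _BW_TABLE
    if _BW_TABLE is None:
        text = resources.files("dosecontrol.data").joinpath(
            "body_weight_by_age_sex.json").read_text()
        _BW_TABLE = json.loads(text)["bins"]
    return _BW_TABLE


def impute_body_weight(age: float, sex: int) -> float:
    """Population-mean body weight (kg) for the given age and sex.

    Piecewise constant over the bundled age bins; ages outside the table
    are clamped to the nearest bin (with a logged warning).
    """
    if not age > 0:
        raise ValueError("age must be positive")
    key = "M" if sex == 1 else "F"
    bins = _bw_table()
    lo, hi = bins[0]["lo"], bins[-1]["hi"]
    if age < lo or age >= hi:
        logger.warning("age %.1f outside body-weight table [%s, %s); clamped",
                       age, lo, hi)
        age = min(max(age, lo), hi - 1e-9)
    for b in bins:
        if b["lo"] <= age < b["hi"]:
            return float(b[key])
    raise RuntimeError("unreachable: body-weight table bins do not cover age")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _conc_values(t, times, doses, ka, f, cl, v):
    """Vectorized multi-dose Bateman superposition.

    ``t`` is an array of sample times; ``ka``, ``cl``, ``v`` may be scalars
    or arrays broadcastable against ``t`` (used by the robustness study,
    where a PK parameter is perturbed independently per grid point).
    """
    t = np.asarray(t, dtype=float)
    times = np.asarray(times, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if times.size == 0:
        return np.zeros_like(t)
    ka = np.asarray(ka, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ke = cl / v
    dt = t[..., None] - times  # (..., n_doses)
    active = dt >= 0
    dt = np.where(active, dt, 0.0)
    ka_ = ka[..., None] if ka.ndim else ka
    ke_ = ke[..., None] if ke.ndim else ke
    v_ = v[..., None] if v.ndim else v
    gap = ka_ - ke_
    degenerate = np.abs(gap) < _DEGENERATE_RTOL * ka_
    # regular Bateman term
    with np.errstate(divide="ignore", invalid="ignore"):
        reg = (f * doses * ka_) / (v_ * np.where(degenerate, 1.0, gap)) * (
            np.exp(-ke_ * dt) - np.exp(-ka_ * dt))
    # ka -> ke limit: f*D*ka/v * dt * exp(-ka dt)
    lim = (f * doses * ka_) / v_ * dt * np.exp(-ka_ * dt)
    term = np.where(degenerate, lim, reg)
    return np.sum(np.where(active, term, 0.0), axis=-1)


def concentration(t, schedule: DoseSchedule, pk: PKParameters):
    """Blood concentration C(t) in mg/L at time(s) ``t`` (hours).

    Closed-form multi-dose superposition; exactly 0 before the first dose.
    Accepts a scalar or an array of times.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    vals = _conc_values(np.atleast_1d(np.asarray(t, dtype=float)),
                        schedule.times, schedule.doses,
                        pk.ka, pk.f, pk.clearance, pk.volume)
    return float(vals[0]) if scalar else vals


def sample_profile(schedule: DoseSchedule, pk: PKParameters,
                   grid_minutes: float = 1.0) -> ConcentrationProfile:
    """Sample the closed-form profile on a uniform grid over the horizon."""
    t_in, t_fin = schedule.horizon
    n = int(round((t_fin - t_in) * 60.0 / grid_minutes)) + 1
    grid = np.linspace(t_in, t_fin, n)
    values = concentration(grid, schedule, pk)
    return ConcentrationProfile(grid=grid, values=values, schedule=schedule, pk=pk)


def exposure_integral(schedule: DoseSchedule, pk: PKParameters,
                      t0: float, t1: float) -> float:
    """Exact integral of C(t) from t0 to t1 (t1 may be ``np.inf``), mg*h/L.

    Uses the analytic antiderivative of each Bateman term; this is the
    primitive behind AUC and the target-distance cost integrals.
    """
    if not t0 < t1:
        raise ValueError("integration bounds must satisfy t0 < t1")
    ka, f, ke, v = pk.ka, pk.f, pk.ke, pk.volume
    total = 0.0
    for ti, d in zip(schedule.times, schedule.doses):
        if ti >= t1 or d == 0:
            continue
        s0 = max(t0, ti) - ti
        s1 = t1 - ti
        e_ke0 = np.exp(-ke * s0)
        e_ka0 = np.exp(-ka * s0)
        e_ke1 = 0.0 if np.isinf(s1) else np.exp(-ke * s1)
        e_ka1 = 0.0 if np.isinf(s1) else np.exp(-ka * s1)
        if abs(ka - ke) < _DEGENERATE_RTOL * ka:
            # int s e^{-ka s} ds = -(s/ka + 1/ka^2) e^{-ka s}
            def anti(s, e):
                return -(s / ka + 1.0 / ka ** 2) * e
            upper = 0.0 if np.isinf(s1) else anti(s1, e_ka1)
            total += (f * d * ka / v) * (upper - anti(s0, e_ka0))
        else:
            coef = f * d * ka / (v * (ka - ke))
            total += coef * ((e_ke0 - e_ke1) / ke - (e_ka0 - e_ka1) / ka)
    return float(total)


def auc(profile: ConcentrationProfile, t0: float, t1: float) -> float:
    """Area under the concentration curve on [t0, t1], mg*h/L (exact)."""
    return exposure_integral(profile.schedule, profile.pk, t0, t1)


def time_average_concentration(schedule: DoseSchedule, pk: PKParameters,
                               t0: float, t1: float) -> float:
    """Mean concentration over [t0, t1] in mg/L."""
    return exposure_integral(schedule, pk, t0, t1) / (t1 - t0)


def fraction_time_above(profile: ConcentrationProfile, threshold: float) -> float:
    """Fraction of the horizon with C(t) >= threshold, on the profile grid.

    The default profile grid is 1-minute; the estimate is the fraction of
    grid points at or above the threshold.
    """
    if threshold <= 0:
        return 1.0
    return float(np.mean(profile.values >= threshold))


def threshold_crossings(schedule: DoseSchedule, pk: PKParameters,
                        threshold: float, t0: float, t1: float,
                        grid_minutes: float = 1.0) -> list:
    """Times in (t0, t1) where C(t) crosses the threshold.

    Sign changes are bracketed on a fine grid and refined by bisection on
    the closed form; the concentration varies on multi-hour timescales, so
    a 1-minute bracketing grid cannot miss a crossing in practice.
    """
    n = int(round((t1 - t0) * 60.0 / grid_minutes)) + 1
    grid = np.linspace(t0, t1, n)
    vals = concentration(grid, schedule, pk) - threshold
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    out = []
    for i in idx:
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            out.append(float(a))
            continue
        if fa * fb < 0:
            out.append(float(brentq(
                lambda t: concentration(t, schedule, pk) - threshold, a, b,
                xtol=1e-10)))
    return out


# ---------------------------------------------------------------------------
# schedule helpers
# ---------------------------------------------------------------------------

def standard_schedule(days: float,
                      daily_dose_mg: float = STANDARD_DAILY_DOSE_MG,
                      doses_per_day: int = 1) -> DoseSchedule:
    """The standard fixed regimen: ``daily_dose_mg`` split over
    ``doses_per_day`` equal doses per day for ``days`` days."""
    n = int(round(days * doses_per_day))
    interval = HOURS_PER_DAY / doses_per_day
    times = np.arange(n) * interval
    doses = np.full(n, daily_dose_mg / doses_per_day)
    return DoseSchedule(times=tuple(times), doses=tuple(doses),
                        horizon=(0.0, days * HOURS_PER_DAY))


def standard_time_average(pk: PKParameters, window_days: float = 40.0,
                          daily_dose_mg: float = STANDARD_DAILY_DOSE_MG,
                          doses_per_day: int = 1) -> float:
    """Time-average concentration C-bar over a standard-therapy window
    (default: 40 days of 400 mg/day), the quantity feeding EC50 estimation."""
    sched = standard_schedule(window_days, daily_dose_mg, doses_per_day)
    return time_average_concentration(sched, pk, 0.0, window_days * HOURS_PER_DAY)
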