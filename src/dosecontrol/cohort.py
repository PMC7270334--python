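"""Seeded synthetic cohorts and tumor-burden series.

These generators emulate the statistical structure the pipeline assumes —
a demographic cohort driving covariate PK models, and BCR-ABL burden series
decaying biphasically in log10 scale with additive measurement noise,
sampled at the 90-day clinic-visit cadence.  Defaults loosely mirror the
shape of published CML monitoring cohorts (majority male, ~2700-day
follow-up, 90-day draws); everything is overridable and the generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import PatientRecord
from .tumor import BurdenSeries


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a demographic cohort."""

    n_patients: int = 22
    male_fraction: float = 18 / 22
    age_mean: float = 50.0
    age_sd: float = 15.0
    age_bounds: tuple = (18.0, 85.0)
    bw_mean_male: float = 85.0
    bw_sd_male: float = 12.0
    bw_bounds_male: tuple = (50.0, 130.0)
    bw_mean_female: float = 72.0
    bw_sd_female: float = 12.0
    bw_bounds_female: tuple = (40.0, 120.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        for lo, hi in (self.age_bounds, self.bw_bounds_male,
                       self.bw_bounds_female):
            if not lo < hi:
                raise ValueError("bounds must satisfy lo < hi")


@dataclass(frozen=True)
class BurdenGenSpec:
    """Two-line log10 decay with additive noise, sampled every 90 days.

    The canonical responder has slope1 < slope2 < 0: a steep initial decline
    (differentiated-cell clearance entangled with healthy recovery) followed
    by a slower pure-CSC decay.  The second line is anchored to the first at
    the breakpoint, so the noiseless curve is continuous.
    """

    slope1: float = -0.01
    slope2: float = -0.001
    breakpoint: float = 300.0
    initial_burden: float = 1.0
    noise_sd: float = 0.15
    sampling_interval: float = 90.0
    duration: float = 2700.0
    seed: int = 0

    def __post_init__(self):
        if not (self.slope1 < self.slope2 < 0):
            raise ValueError("canonical responder requires slope1 < slope2 < 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.breakpoint < self.duration:
            raise ValueError("breakpoint must lie inside the duration")
        if not (self.sampling_interval > 0 and self.initial_burden > 0):
            raise ValueError("sampling_interval and initial_burden must be "
                             "positive")


def _truncated_normal(rng, mean, sd, bounds, size):
    """Resample out-of-bounds draws (errors out if bounds are hopeless)."""
    if sd == 0:
        if not bounds[0] <= mean <= bounds[1]:
            raise ValueError("degenerate distribution outside bounds")
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if filled == size:
            return out
    raise ValueError(f"could not sample within bounds {bounds} "
                     f"(mean={mean}, sd={sd})")


def generate_cohort(spec: CohortSpec) -> list:
    """Seeded, reproducible list of PatientRecord."""
    rng = np.random.default_rng(spec.seed)
    sexes = (rng.random(spec.n_patients) < spec.male_fraction).astype(int)
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_bounds,
                             spec.n_patients)
    patients = []
    for i, (sex, age) in enumerate(zip(sexes, ages)):
        if sex == 1:
            bw = _truncated_normal(rng, spec.bw_mean_male, spec.bw_sd_male,
                                   spec.bw_bounds_male, 1)[0]
        else:
            bw = _truncated_normal(rng, spec.bw_mean_female, spec.bw_sd_female,
                                   spec.bw_bounds_female, 1)[0]
        patients.append(PatientRecord(id=f"SYN{i:04d}", age=float(age),
                                      sex=int(sex), body_weight=float(bw)))
    return patients


def biphasic_log10(spec: BurdenGenSpec, t) -> np.ndarray:
    """Noiseless log10 burden of the generating two-line model."""
    t = np.asarray(t, dtype=float)
    i1 = np.log10(spec.initial_burden)
    left = i1 + spec.slope1 * t
    value_at_bp = i1 + spec.slope1 * spec.breakpoint
    right = value_at_bp + spec.slope2 * (t - spec.breakpoint)
    return np.where(t <= spec.breakpoint, left, right)


def generate_burden_series(spec: BurdenGenSpec,
                           patient_id: str = "SYN0000") -> BurdenSeries:
    """Sample the biphasic model at the clinic cadence with log10 noise."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration + 0.5 * spec.sampling_interval,
                      spec.sampling_interval)
    log_b = biphasic_log10(spec, times)
    if spec.noise_sd > 0:
        log_b = log_b + rng.normal(0.0, spec.noise_sd, size=times.shape)
    return BurdenSeries(patient_id=patient_id, times=tuple(times),
                        burden=tuple(10.0 ** log_b))
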