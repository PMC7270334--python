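"""Emax pharmacodynamics and patient-specific EC50 estimation.

Drug effect follows the saturating maximum-inhibition curve

    E(C) = Emax * C^n / (EC50^n + C^n)

and the cohort-level link between effect and CSC kill is taken linear,
<d1> = K <E>, with conversion constant K (1/day).  K is estimated on a
cohort by pairing each patient's 40-day time-average concentration under
standard therapy (via their covariate PK model) with the CSC death rate
fitted from their burden series, using one benchmark PD curve
(Emax = 1, n = 1, EC50 = 0.123 mg/L) for everyone.  Given K, a
patient-specific EC50 follows by inverting d1 = K * E(C-bar):

    EC50_j = C-bar_j * (K * Emax / d1_j - 1)^(1/n)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError

#: benchmark half-maximal concentration for imatinib, mg/L
BENCHMARK_EC50 = 0.123


@dataclass(frozen=True)
class PDParameters:
    """Emax-model parameters."""

    emax: float = 1.0
    ec50: float = BENCHMARK_EC50
    n: float = 1.0

    def __post_init__(self):
        if not (self.emax > 0 and self.ec50 > 0 and self.n > 0):
            raise ValueError("emax, ec50 and n must all be positive")


@dataclass(frozen=True)
class ConversionConstant:
    """Effect-to-death-rate constant K (1/day) with CI half-width."""

    k: float
    k_ci: float = 0.0

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("conversion constant K must be positive")


BENCHMARK_PD = PDParameters(emax=1.0, ec50=BENCHMARK_EC50, n=1.0)


def efficacy(c, pd: PDParameters = BENCHMARK_PD):
    """Effect E(C) of concentration(s) ``c`` (mg/L); dimensionless, < Emax."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = c ** pd.n
    out = pd.emax * cn / (pd.ec50 ** pd.n + cn)
    return float(out) if out.ndim == 0 else out


def estimate_conversion(d1_values: Sequence[float],
                        mean_efficacies: Sequence[float],
                        d1_standard_errors: Sequence[float] | None = None,
                        ) -> ConversionConstant:
    """Cohort conversion constant K = mean(d1) / mean(E-bar).

    ``mean_efficacies`` are the per-patient benchmark efficacies evaluated at
    each patient's standard-therapy time-average concentration.  The CI
    half-width propagates the d1 standard errors linearly, treating patients
    as independent: sd(K) = sqrt(sum se_j^2) / (n * <E>).
    """
    d1 = np.asarray(d1_values, dtype=float)
    eff = np.asarray(mean_efficacies, dtype=float)
    if d1.size == 0 or d1.size != eff.size:
        raise ValueError("need equally many d1 values and efficacies")
    mean_e = float(eff.mean())
    if mean_e == 0:
        raise EstimationError("zero mean efficacy: cannot form K")
    k = float(d1.mean()) / mean_e
    ci = 0.0
    if d1_standard_errors is not None:
        se = np.asarray(d1_standard_errors, dtype=float)
        ci = float(np.sqrt(np.sum(se ** 2)) / (d1.size * mean_e))
    return ConversionConstant(k=k, k_ci=ci)


def estimate_ec50(c_bar: float, conversion: ConversionConstant, d1: float,
                  emax: float = 1.0, n: float = 1.0) -> float:
    """Patient EC50 (mg/L) inverting d1 = K * E(C-bar)."""
    if not c_bar > 0:
        raise ValueError("time-average concentration must be positive")
    bracket = conversion.k * emax / d1 - 1.0
    if d1 <= 0 or bracket <= 0:
        raise EstimationError(
            f"d1={d1:.4g} must lie in (0, K*Emax)={conversion.k * emax:.4g} "
            "for the Emax inversion to have a solution")
    return float(c_bar * bracket ** (1.0 / n))
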