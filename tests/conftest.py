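"""Shared fixtures.

The lower-bound optimization of the average male patient is the workhorse
scenario (it backs the coverage, robustness and optimizer-sanity checks),
so it runs once per session and is shared.
"""

import numpy as np
import pytest

import dosecontrol as dc
from dosecontrol.control import ControlProblem, OptimizerConfig, dcrab_optimize
from dosecontrol.units import HOURS_PER_DAY

LOWER_BOUND = 0.57
HORIZON_DAYS = 14.0


@pytest.fixture(scope="session")
def coeffs():
    return dc.load_pk_constants()


@pytest.fixture(scope="session")
def average_male(coeffs):
    return dc.reference_patient(sex=1, coeffs=coeffs)


@pytest.fixture(scope="session")
def average_male_pk(average_male, coeffs):
    return dc.pk_from_covariates(average_male, coeffs)


@pytest.fixture(scope="session")
def lower_bound_problem(average_male_pk):
    return ControlProblem(
        horizon=(0.0, HORIZON_DAYS * HOURS_PER_DAY),
        n_doses=int(HORIZON_DAYS),
        cost_kind="lower_bound",
        pk=average_male_pk,
        target_conc=LOWER_BOUND,
    )


@pytest.fixture(scope="session")
def optimized_lower_bound(lower_bound_problem):
    """One-dose-per-day lower-bound optimization, default budgets, seed 1."""
    return dcrab_optimize(lower_bound_problem, OptimizerConfig(), seed=1)
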