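"""Covariate PK model and multi-dose closed-form concentration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

import dosecontrol as dc
from dosecontrol.errors import InvalidCovariatesError
from dosecontrol.pk import PKCovariateCoefficients, PKParameters, DoseSchedule

COEFFS = PKCovariateCoefficients(
    theta_a=14.3, theta_b=347.0, theta_1=5.5, theta_2=0.8, theta_3=-1.3,
    theta_4=25.0, bw_mean=70.0, age_mean=50.0, ka=0.61, f=1.0)


def _patient(sex=1, age=50.0, bw=70.0):
    return dc.PatientRecord(id="p", age=age, sex=sex, body_weight=bw)


class TestCovariateModel:
    def test_male_at_population_means(self):
        cl = dc.clearance_from_covariates(_patient(sex=1), COEFFS)
        assert cl == pytest.approx(COEFFS.theta_a + COEFFS.theta_2)

    def test_female_at_population_means(self):
        cl = dc.clearance_from_covariates(_patient(sex=0), COEFFS)
        assert cl == pytest.approx(COEFFS.theta_a - COEFFS.theta_2)

    def test_arbitrary_patient_matches_hand_evaluation(self):
        p = _patient(sex=0, age=63.0, bw=58.5)
        expected = (14.3 + 5.5 * (58.5 - 70.0) / 70.0 - 0.8
                    - 1.3 * (63.0 - 50.0) / 50.0)
        assert dc.clearance_from_covariates(p, COEFFS) == pytest.approx(
            expected, rel=1e-12)

    def test_volume_by_sex_and_symmetry(self):
        v_m = dc.volume_from_covariates(_patient(sex=1), COEFFS)
        v_f = dc.volume_from_covariates(_patient(sex=0), COEFFS)
        assert v_m == pytest.approx(COEFFS.theta_b + COEFFS.theta_4)
        assert v_f == pytest.approx(COEFFS.theta_b - COEFFS.theta_4)
        assert 0.5 * (v_m + v_f) == pytest.approx(COEFFS.theta_b)

    def test_nonpositive_clearance_rejected(self):
        bad = PKCovariateCoefficients(
            theta_a=1.0, theta_b=347.0, theta_1=5.5, theta_2=2.0,
            theta_3=-1.3, theta_4=25.0, bw_mean=70.0, age_mean=50.0,
            ka=0.61, f=1.0)
        with pytest.raises(InvalidCovariatesError, match="clearance"):
            dc.clearance_from_covariates(_patient(sex=0), bad)


class TestBodyWeightImputation:
    def test_lookup_is_piecewise_constant(self):
        assert dc.impute_body_weight(42.0, 1) == dc.impute_body_weight(48.9, 1)

    def test_sexes_differ(self):
        assert dc.impute_body_weight(45.0, 1) != dc.impute_body_weight(45.0, 0)

    def test_out_of_range_age_clamps(self):
        assert dc.impute_body_weight(150.0, 0) == dc.impute_body_weight(95.0, 0)


@pytest.fixture(scope="module")
def pk():
    return PKParameters(ka=0.61, f=1.0, clearance=15.1, volume=372.0)


@pytest.fixture(scope="module")
def three_daily(pk):
    return dc.standard_schedule(14, doses_per_day=3)


def _ode_profile(schedule, pk, t_eval):
    """Numerical integration of the depot/blood ODE pair with impulsive
    dosing; the independent oracle for the closed form."""
    def rhs(t, y):
        return [-pk.ka * y[0],
                pk.ka * y[0] - pk.clearance * y[1] / pk.volume]

    times = list(schedule.times)
    edges = times + [schedule.horizon[1]]
    y = np.array([0.0, 0.0])
    out_t, out_c = [], []
    for i, td in enumerate(times):
        y[0] += pk.f * schedule.doses[i]
        seg = np.unique(np.append(
            t_eval[(t_eval >= td) & (t_eval < edges[i + 1])], edges[i + 1]))
        sol = solve_ivp(rhs, (td, edges[i + 1]), y, t_eval=seg,
                        rtol=1e-11, atol=1e-14, method="DOP853", max_step=4.0)
        out_t.append(sol.t)
        out_c.append(sol.y[1] / pk.volume)
        y = sol.y[:, -1].copy()
    return np.concatenate(out_t), np.concatenate(out_c)


class TestConcentration:
    def test_empty_schedule_and_causality(self, pk):
        empty = DoseSchedule(times=(), doses=(), horizon=(0.0, 24.0))
        assert dc.concentration(10.0, empty, pk) == 0.0
        sched = DoseSchedule(times=(5.0,), doses=(400.0,), horizon=(0.0, 24.0))
        assert dc.concentration(4.999, sched, pk) == 0.0
        assert dc.concentration(5.5, sched, pk) > 0.0

    def test_closed_form_matches_ode_oracle(self, pk, three_daily):
        t = np.linspace(0.0, 336.0, 1500)
        tt, c_ode = _ode_profile(three_daily, pk, t)
        c_cf = dc.concentration(tt, three_daily, pk)
        scale = np.maximum(np.abs(c_ode), 1e-9 * c_ode.max())
        assert np.max(np.abs(c_cf - c_ode) / scale) < 1e-6

    def test_superposition(self, pk):
        sched = DoseSchedule(times=(0.0, 24.0, 48.0), doses=(400.0, 300.0, 500.0),
                             horizon=(0.0, 96.0))
        t = np.linspace(0.0, 96.0, 300)
        total = dc.concentration(t, sched, pk)
        parts = sum(
            dc.concentration(t, DoseSchedule(times=(ti,), doses=(di,),
                                             horizon=(0.0, 96.0)), pk)
            for ti, di in zip(sched.times, sched.doses))
        np.testing.assert_allclose(total, parts, rtol=1e-12, atol=1e-15)

    def test_dose_linearity(self, pk):
        sched = dc.standard_schedule(7)
        scaled = DoseSchedule(times=sched.times,
                              doses=tuple(2.5 * d for d in sched.doses),
                              horizon=sched.horizon)
        t = np.linspace(0.0, 168.0, 200)
        np.testing.assert_allclose(dc.concentration(t, scaled, pk),
                                   2.5 * dc.concentration(t, sched, pk),
                                   rtol=1e-12)
        assert dc.exposure_integral(scaled, pk, 0, 168) == pytest.approx(
            2.5 * dc.exposure_integral(sched, pk, 0, 168), rel=1e-12)

    def test_degenerate_equal_rates_limit(self):
        # ka == ke: Bateman collapses to f*D*ka/v * t * exp(-ka t)
        pk_eq = PKParameters(ka=0.05, f=1.0, clearance=0.05 * 372.0,
                             volume=372.0)
        sched = DoseSchedule(times=(0.0,), doses=(400.0,), horizon=(0.0, 96.0))
        t = np.linspace(0.0, 96.0, 200)
        got = dc.concentration(t, sched, pk_eq)
        expected = 400.0 * 0.05 / 372.0 * t * np.exp(-0.05 * t)
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(ka=st.floats(0.05, 5.0), cl=st.floats(1.0, 50.0),
           v=st.floats(20.0, 500.0), t=st.floats(0.0, 400.0))
    def test_nonnegative_everywhere(self, ka, cl, v, t):
        pk_rand = PKParameters(ka=ka, f=1.0, clearance=cl, volume=v)
        sched = dc.standard_schedule(14)
        assert dc.concentration(t, sched, pk_rand) >= 0.0


class TestExposure:
    def test_zero_schedule(self, pk):
        empty = DoseSchedule(times=(), doses=(), horizon=(0.0, 24.0))
        assert dc.exposure_integral(empty, pk, 0.0, 24.0) == 0.0

    def test_single_dose_to_infinity_is_fd_over_cl(self, pk):
        sched = DoseSchedule(times=(0.0,), doses=(400.0,), horizon=(0.0, 1e7))
        got = dc.exposure_integral(sched, pk, 0.0, np.inf)
        assert got == pytest.approx(pk.f * 400.0 / pk.clearance, rel=1e-8)

    def test_matches_adaptive_quadrature(self, pk, three_daily):
        got = dc.exposure_integral(three_daily, pk, 10.0, 100.0)
        ref, _ = quad(lambda t: dc.concentration(t, three_daily, pk),
                      10.0, 100.0, limit=400,
                      points=[t for t in three_daily.times if 10 < t < 100])
        assert got == pytest.approx(ref, rel=1e-9)

    def test_reversed_bounds_rejected(self, pk, three_daily):
        with pytest.raises(ValueError):
            dc.exposure_integral(three_daily, pk, 10.0, 5.0)

    def test_time_average_of_zero_schedule(self, pk):
        empty = DoseSchedule(times=(), doses=(), horizon=(0.0, 24.0))
        assert dc.time_average_concentration(empty, pk, 0.0, 24.0) == 0.0

    def test_forty_day_average_equals_auc_over_960h(self, pk):
        sched = dc.standard_schedule(40)
        avg = dc.standard_time_average(pk)
        assert avg == pytest.approx(
            dc.exposure_integral(sched, pk, 0, 960.0) / 960.0, rel=1e-12)


class TestFractionAbove:
    def test_trivial_thresholds(self, pk):
        prof = dc.sample_profile(dc.standard_schedule(3), pk)
        assert dc.fraction_time_above(prof, 0.0) == 1.0
        assert dc.fraction_time_above(prof, prof.values.max() + 1.0) == 0.0

    def test_matches_root_finding_oracle(self, pk):
        # single dose: crosses the threshold exactly twice
        sched = DoseSchedule(times=(0.0,), doses=(400.0,), horizon=(0.0, 72.0))
        prof = dc.sample_profile(sched, pk)
        thr = 0.5
        f = lambda t: dc.concentration(t, sched, pk) - thr
        t_peak = np.log(pk.ka / pk.ke) / (pk.ka - pk.ke)
        up = brentq(f, 1e-6, t_peak)
        down = brentq(f, t_peak, 72.0)
        expected = (down - up) / 72.0
        assert dc.fraction_time_above(prof, thr) == pytest.approx(
            expected, abs=2.0 / (72 * 60))  # within grid resolution
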