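"""Cost functionals, Fourier dose corrections, discretization, optimizer."""

import numpy as np
import pytest

import dosecontrol as dc
from dosecontrol.control import (ControlProblem, FourierCorrection,
                                 OptimizerConfig, build_dose_function,
                                 constant_rate, cost_burden_auc,
                                 cost_lower_bound, cost_optimal_target,
                                 dcrab_optimize, discretize_doses, dose_times,
                                 evaluate_cost, integrate_rate, phi_scan)
from dosecontrol.emax import ConversionConstant, PDParameters
from dosecontrol.pk import DoseSchedule, PKParameters
from dosecontrol.tumor import LOG10_E, LeukemiaParams

PK = PKParameters(ka=0.61, f=1.0, clearance=15.1, volume=372.0)
HORIZON = (0.0, 336.0)

SMALL = OptimizerConfig(n_frequencies=3, evals_per_superiteration=40,
                        grid_minutes=2.0)


def _profile(days=14.0, doses_per_day=1):
    sched = dc.standard_schedule(days, doses_per_day=doses_per_day)
    return dc.sample_profile(sched, PK, grid_minutes=5.0)


def _riemann(profile, integrand, seconds=5.0):
    t_in, t_fin = profile.schedule.horizon
    t = np.arange(t_in, t_fin, seconds / 3600.0)
    c = dc.concentration(t, profile.schedule, profile.pk)
    return float(np.sum(integrand(c)) * (seconds / 3600.0))


class TestTargetCosts:
    def test_target_above_whole_profile_is_exact(self):
        prof = _profile()
        c_tg = prof.values.max() + 1.0
        T = HORIZON[1]
        expected = c_tg * T - dc.exposure_integral(prof.schedule, PK, *HORIZON)
        assert cost_optimal_target(prof, c_tg) == pytest.approx(
            expected, rel=1e-9)
        # below the floor everywhere -> flat penalty over the horizon
        assert cost_lower_bound(prof, c_tg, g_penalty=3.0) == pytest.approx(
            3.0 * T, rel=1e-12)

    def test_optimal_target_matches_riemann_oracle(self):
        prof = _profile()
        got = cost_optimal_target(prof, 1.0)
        ref = _riemann(prof, lambda c: np.abs(c - 1.0))
        assert got == pytest.approx(ref, rel=1e-4)

    def test_lower_bound_matches_split_integral_oracle(self):
        prof = _profile()
        c_tg, g = 0.57, 5.7
        got = cost_lower_bound(prof, c_tg, g)
        ref = _riemann(prof, lambda c: np.where(c >= c_tg, c - c_tg, g))
        assert got == pytest.approx(ref, rel=1e-4)

    def test_lower_bound_requires_positive_penalty(self):
        with pytest.raises(ValueError):
            cost_lower_bound(_profile(), 0.57, g_penalty=0.0)


class TestBurdenCost:
    LEO = LeukemiaParams(a1=0.87, p1=0.45, d1=0.0)
    PD = PDParameters(emax=1.0, ec50=0.123, n=1.0)
    CONV = ConversionConstant(k=0.377)

    def test_pure_toxicity_limit_is_auc(self):
        prof = _profile()
        got = cost_burden_auc(prof, self.PD, self.LEO, self.CONV, 0.0, 2.0)
        auc = dc.exposure_integral(prof.schedule, PK, *HORIZON)
        assert got == pytest.approx(2.0 * auc / 24.0, rel=1e-9)

    def test_no_drug_limit_is_untreated_growth(self):
        empty = DoseSchedule(times=(), doses=(), horizon=HORIZON)
        prof = dc.sample_profile(empty, PK, grid_minutes=30.0)
        got = cost_burden_auc(prof, self.PD, self.LEO, self.CONV, 3.0, 0.0)
        lam0 = (2 * 0.87 - 1) * 0.45
        assert got == pytest.approx(3.0 * LOG10_E * lam0 * 14.0, rel=1e-9)

    def test_generic_matches_dense_grid_oracle(self):
        prof = _profile(doses_per_day=3)
        got = cost_burden_auc(prof, self.PD, self.LEO, self.CONV, 60.0, 1.0)

        def integrand(c):
            lam0 = (2 * 0.87 - 1) * 0.45
            eff = c / (0.123 + c)
            return (60.0 * LOG10_E * (lam0 - 0.377 * eff) + 1.0 * c) / 24.0

        ref = _riemann(prof, integrand)
        assert got == pytest.approx(ref, rel=1e-4)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            cost_burden_auc(_profile(), self.PD, self.LEO, self.CONV, 0.0, 0.0)


class TestDoseFunction:
    def _correction(self, amps):
        return FourierCorrection(amplitudes=amps,
                                 r_values=(0.1, -0.3)[:len(amps)],
                                 horizon=HORIZON)

    def test_zero_amplitudes_is_identity(self):
        d0 = constant_rate(400.0)
        d = build_dose_function(d0, self._correction(((0.0, 0.0),)))
        t = np.linspace(0.0, 336.0, 100)
        np.testing.assert_allclose(d(t), d0(t))

    def test_matches_hand_summed_series(self):
        corr = self._correction(((2.0, -1.0), (0.5, 3.0)))
        t = np.linspace(0.0, 336.0, 50)
        w = corr.frequencies()
        hand = corr.envelope(t) * sum(
            a * np.sin(wk * t) + b * np.cos(wk * t)
            for (a, b), wk in zip(corr.amplitudes, w))
        got = build_dose_function(lambda x: np.zeros_like(x), corr)(t)
        np.testing.assert_allclose(got, np.maximum(hand, 0.0), atol=1e-12)

    def test_envelope_vanishes_at_boundaries(self):
        for shape in ("trapezoid", "half_sine"):
            corr = FourierCorrection(amplitudes=((5.0, 5.0),),
                                     r_values=(0.2,), horizon=HORIZON,
                                     gamma_shape=shape)
            assert corr(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)
            assert corr(np.array([336.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_rates_clamped(self):
        corr = self._correction(((0.0, -100.0),))
        d = build_dose_function(constant_rate(400.0), corr)
        assert np.all(d(np.linspace(0, 336, 200)) >= 0.0)


class TestDiscretization:
    def test_constant_rate_gives_equal_doses(self):
        sched, raw = discretize_doses(constant_rate(400.0), 14, HORIZON)
        assert np.allclose(sched.doses, 400.0)
        assert np.allclose(raw, 400.0, rtol=1e-12)
        np.testing.assert_allclose(sched.times, np.arange(14) * 24.0)

    def test_sinusoid_matches_closed_form_antiderivative(self):
        w = 2 * np.pi / 336.0 * 2.3
        d_fn = lambda t: 16.0 + 3.0 * np.sin(w * np.asarray(t))
        sched, raw = discretize_doses(d_fn, 14, HORIZON,
                                      rounding_grain_mg=1.0)
        edges = np.append(dose_times(14, HORIZON), HORIZON[1])
        expected = (16.0 * np.diff(edges)
                    + 3.0 / w * (np.cos(w * edges[:-1]) - np.cos(w * edges[1:])))
        np.testing.assert_allclose(raw, expected, rtol=1e-12)
        # mass conservation: raw doses sum to the full-horizon integral
        total = 16.0 * 336.0 + 3.0 / w * (1.0 - np.cos(w * 336.0))
        assert abs(sum(raw) - total) <= 1e-9 * total

    def test_rounding_and_cap(self):
        d_fn = lambda t: np.full_like(np.asarray(t, float), 416.7 / 24.0)
        sched, raw = discretize_doses(d_fn, 14, HORIZON, dose_max=410.0)
        assert np.allclose(sched.doses, 410.0)       # 416.7 -> 417 -> cap
        assert np.allclose(raw, 416.7, rtol=1e-9)    # raw mass untouched


class TestOptimizer:
    def _problem(self, **kw):
        base = dict(horizon=HORIZON, n_doses=14, cost_kind="lower_bound",
                    pk=PK, target_conc=0.57)
        base.update(kw)
        return ControlProblem(**base)

    def test_deterministic_given_seed(self):
        prob = self._problem()
        r1 = dcrab_optimize(prob, SMALL, seed=5)
        r2 = dcrab_optimize(prob, SMALL, seed=5)
        assert r1.schedule.doses == r2.schedule.doses
        assert r1.cost_trace == r2.cost_trace

    def test_trace_non_increasing_and_bounded_doses(self):
        res = dcrab_optimize(self._problem(), SMALL, seed=2)
        trace = np.asarray(res.cost_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        doses = np.asarray(res.schedule.doses)
        assert np.all(doses >= 0) and np.all(doses <= 800.0)
        assert np.allclose(doses, np.round(doses))  # integer mg

    def test_improves_on_standard_for_optimal_target(self):
        prob = self._problem(cost_kind="optimal_target", target_conc=1.0,
                             n_doses=42)
        cfg = OptimizerConfig(n_frequencies=4, evals_per_superiteration=100,
                              grid_minutes=2.0)
        res = dcrab_optimize(prob, cfg, seed=3)
        std = dc.standard_schedule(14.0, doses_per_day=3)
        std_cost = evaluate_cost(std, prob, cfg.grid_minutes)
        assert res.best_cost <= std_cost + 1e-9

    def test_optional_time_refinement_never_hurts(self):
        cfg = OptimizerConfig(n_frequencies=2, evals_per_superiteration=30,
                              grid_minutes=5.0, optimize_times=True)
        base = OptimizerConfig(n_frequencies=2, evals_per_superiteration=30,
                               grid_minutes=5.0)
        prob = self._problem()
        r_fixed = dcrab_optimize(prob, base, seed=6)
        r_times = dcrab_optimize(prob, cfg, seed=6)
        assert r_times.best_cost <= r_fixed.best_cost + 1e-9
        times = np.asarray(r_times.schedule.times)
        assert np.all(np.diff(times) > 0)
        assert times[0] >= 0.0 and times[-1] <= 336.0

    def test_integrate_rate_panels_consistent(self, optimized_lower_bound):
        # raw dose mass of a real optimized run equals the whole-horizon
        # integral of its dose function
        res = optimized_lower_bound
        d_fn = build_dose_function(constant_rate(400.0), res.correction)
        total = integrate_rate(d_fn, *HORIZON)
        assert abs(sum(res.raw_doses) - total) <= 1e-9 * total


class TestPhiScan:
    LEO = LeukemiaParams(a1=0.87, p1=0.45, d1=0.0)
    CONV = ConversionConstant(k=0.377)

    def test_single_row_consistent_with_standalone_run(self):
        pd = PDParameters(emax=1.0, ec50=0.123, n=1.0)
        df = phi_scan([("p1", PK, pd)], self.LEO, self.CONV, [60.0],
                      config=SMALL, seed=4)
        prob = ControlProblem(horizon=HORIZON, n_doses=14,
                              cost_kind="burden_auc", pk=PK, w1=60.0, w2=1.0,
                              pd=pd, leukemia=self.LEO, conversion=self.CONV)
        res = dcrab_optimize(prob, SMALL, seed=4)
        assert df.loc[0, "best_cost"] == pytest.approx(res.best_cost)

    def test_tuned_phi_speeds_decay_at_similar_exposure(self):
        # phi matched to the standard regimen's exposure level: the
        # optimized schedule clears CSCs at least as fast while keeping
        # the 14-day exposure within 2% of standard therapy
        pd = PDParameters(emax=1.0, ec50=0.123, n=1.0)
        prob = ControlProblem(horizon=HORIZON, n_doses=14,
                              cost_kind="burden_auc", pk=PK, w1=68.0, w2=1.0,
                              pd=pd, leukemia=self.LEO, conversion=self.CONV)
        res = dcrab_optimize(prob, OptimizerConfig(), seed=0)
        std = dc.standard_schedule(14.0)

        def lam(sched):
            c_bar = dc.exposure_integral(sched, PK, *HORIZON) / 336.0
            return ((2 * 0.87 - 1) * 0.45
                    - self.CONV.k * dc.efficacy(c_bar, pd)), c_bar

        lam_opt, c_opt = lam(res.schedule)
        lam_std, c_std = lam(std)
        assert lam_opt <= lam_std + 1e-12
        assert c_opt <= 1.02 * c_std

    def test_phi_limits_steer_exposure(self):
        pd = PDParameters(emax=1.0, ec50=0.123, n=1.0)
        df = phi_scan([("p1", PK, pd)], self.LEO, self.CONV,
                      [0.001, 500.0], config=SMALL, seed=4)
        low = df[df.phi == 0.001].iloc[0]
        high = df[df.phi == 500.0].iloc[0]
        # toxicity-dominated scan shrinks exposure; burden-dominated grows it
        assert low.auc_mg_h_per_L < high.auc_mg_h_per_L
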