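"""Derivative estimation, peak detection and Kissinger fits."""

import math

import numpy as np
import pytest

from conftest import single_step_model
from tgakinetics.curves import TGACurve
from tgakinetics.kinetic import GAS_CONSTANT, integrate
from tgakinetics.kissinger import (
    KissingerAnalysis,
    PeakDetectionError,
    activation_energy_at,
    find_step_peaks,
    kissinger_fit,
    kissinger_quadratic,
    mass_derivative,
    select_E_mode,
)
from tgakinetics.programs import celsius_to_kelvin, make_linear_ramp, rate_per_min_to_per_s


def _linear_curve(slope=-0.001, n=500):
    T = np.linspace(100, 400, n)
    return TGACurve(t=np.arange(n, dtype=float), T_C=T, m=1.0 + slope * (T - T[0]))


class TestMassDerivative:
    def test_exact_for_linear_data(self):
        d = mass_derivative(_linear_curve(slope=-0.001))
        assert np.allclose(d.dm_dT, -0.001, atol=1e-12)

    def test_zero_for_constant_mass(self):
        c = _linear_curve(slope=0.0)
        d = mass_derivative(c)
        assert np.allclose(d.dm_dT, 0.0, atol=1e-15)

    def test_small_span_rejected(self):
        c = TGACurve(t=np.arange(20.0), T_C=np.linspace(0, 3, 20), m=np.ones(20))
        with pytest.raises(ValueError):
            mass_derivative(c)

    def test_non_monotone_temperature_rejected(self):
        T = np.linspace(100, 300, 50)
        T[25] = 90.0
        c = TGACurve(t=np.arange(50.0), T_C=T, m=np.ones(50))
        with pytest.raises(ValueError, match="resample"):
            mass_derivative(c)

    def test_single_step_inflection_location(self):
        # peak of -dm/dT located by brute-force search on a dense noiseless
        # forward model must match the derivative-estimator location
        model = single_step_model()
        q = 10.0
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(q)
        )
        dense = prog.time_grid(n=20000)
        traj = integrate(model, prog, dense)
        truth_T = traj.T_C[np.argmax(-np.gradient(traj.m, traj.T))]

        grid = prog.time_grid(n=3000)
        traj2 = integrate(model, prog, grid)
        curve = TGACurve(t=grid, T_C=traj2.T_C, m=traj2.m)
        d = mass_derivative(curve)
        est_T = d.T_C[np.argmin(d.dm_dT)]
        assert abs(est_T - truth_T) < 0.5


class TestFindStepPeaks:
    def test_flat_signal_errors(self):
        d = mass_derivative(_linear_curve(slope=0.0))
        with pytest.raises(PeakDetectionError):
            find_step_peaks(d, n_steps=1)

    def test_single_step_curve(self):
        model = single_step_model()
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(10)
        )
        traj = integrate(model, prog, prog.time_grid(n=3000))
        d = mass_derivative(TGACurve(t=traj.t, T_C=traj.T_C, m=traj.m))
        peaks = find_step_peaks(d, n_steps=1)
        assert len(peaks) == 1

    def test_too_many_steps_requested(self):
        model = single_step_model()
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(10)
        )
        traj = integrate(model, prog, prog.time_grid(n=3000))
        d = mass_derivative(TGACurve(t=traj.t, T_C=traj.T_C, m=traj.m))
        with pytest.raises(PeakDetectionError):
            find_step_peaks(d, n_steps=3)

    def test_three_step_study_peaks_ordered_and_near_truth(self, mini_noiseless_study):
        # truth locations from the dense noiseless forward model at q = 10
        c10 = [c for c in mini_noiseless_study if c.q_plus == 10][0]
        d = mass_derivative(c10)
        peaks = find_step_peaks(d, n_steps=3)
        assert peaks == sorted(peaks)
        for found, truth in zip(peaks, (268.0, 315.1, 362.0)):
            assert abs(found - truth) < 1.0


class TestKissingerFit:
    def _exact_points(self, E=150e3, const=10.0, Tps=(500, 520, 540, 560, 580)):
        Tp = np.array(Tps, dtype=float)
        y = -E / (GAS_CONSTANT * Tp) + const
        q_K_s = np.exp(y) * Tp**2
        return q_K_s * 60.0, Tp  # q in degC/min

    def test_exact_line_recovers_E(self):
        q, Tp = self._exact_points(E=150e3)
        res = kissinger_fit(q, Tp)
        assert res.E == pytest.approx(150e3, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            kissinger_fit([1.0, 2.0], [500.0, 510.0])

    def test_duplicate_Tp_rejected(self):
        with pytest.raises(ValueError):
            kissinger_fit([1.0, 2.0, 3.0], [500.0, 500.0, 510.0])

    def test_unit_invariance_of_slope(self):
        q, Tp = self._exact_points()
        res_min = kissinger_fit(q, Tp)
        res_sec = kissinger_fit(q * 60.0, Tp)  # pretend q was per-second scale
        assert res_min.E == pytest.approx(res_sec.E, rel=1e-12)
        assert res_min.intercept != pytest.approx(res_sec.intercept)

    def test_forward_simulated_single_step_within_3pct(self):
        # Kissinger is an approximation for autocatalytic kinetics; the
        # fitted E must still come out within a few percent of truth.
        E_true = 150e3
        model = single_step_model(E=E_true, A=1e12, M=0.3, N=1.2)
        tps, qs = [], (0.5, 1, 2, 5, 10, 20)
        for q in qs:
            prog = make_linear_ramp(
                celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(q)
            )
            traj = integrate(model, prog, prog.time_grid(n=3000))
            d = mass_derivative(TGACurve(t=traj.t, T_C=traj.T_C, m=traj.m))
            tps.append(celsius_to_kelvin(find_step_peaks(d, n_steps=1)[0]))
        res = kissinger_fit(np.array(qs), np.array(tps))
        assert abs(res.E - E_true) / E_true < 0.03


class TestQuadraticMode:
    def _curved_points(self, b=-18000.0, c=-2.0e6, a=5.0, Tps=(480, 500, 520, 540, 560, 580)):
        Tp = np.array(Tps, dtype=float)
        x = 1.0 / Tp
        y = a + b * x + c * x**2
        q = np.exp(y) * Tp**2 * 60.0
        return q, Tp

    def test_degenerate_quadratic_is_constant_E(self):
        q, Tp = self._curved_points(c=0.0, b=-150e3 / GAS_CONSTANT)
        res = kissinger_quadratic(q, Tp)
        for T in (500.0, 550.0):
            assert activation_energy_at(res, T) == pytest.approx(150e3, rel=1e-9)

    def test_prescribed_coefficients_reproduced(self):
        b, c = -18000.0, -2.0e6
        q, Tp = self._curved_points(b=b, c=c)
        res = kissinger_quadratic(q, Tp)
        assert res.b == pytest.approx(b, rel=1e-9)
        assert res.c == pytest.approx(c, rel=1e-9)
        for T in (500.0, 540.0, 575.0):
            assert activation_energy_at(res, T) == pytest.approx(
                -GAS_CONSTANT * (b + 2 * c / T), rel=1e-9
            )

    def test_outside_window_raises(self):
        q, Tp = self._curved_points()
        res = kissinger_quadratic(q, Tp)
        with pytest.raises(ValueError):
            activation_energy_at(res, 700.0)

    def test_collinear_selects_linear(self):
        q, Tp = self._curved_points(c=0.0, b=-150e3 / GAS_CONSTANT)
        assert select_E_mode(q, Tp) == "linear"

    def test_strong_curvature_selects_quadratic(self):
        q, Tp = self._curved_points(b=-18000.0, c=-2.0e6)
        assert select_E_mode(q, Tp) == "quadratic"

    def test_mild_noise_keeps_linear(self):
        rng = np.random.default_rng(0)
        Tp = np.array([500, 520, 540, 560, 580.0])
        y = -150e3 / (GAS_CONSTANT * Tp) + 10 + rng.normal(0, 0.01, len(Tp))
        q = np.exp(y) * Tp**2 * 60.0
        assert select_E_mode(q, Tp) == "linear"


class TestKissingerAnalysis:
    def test_study_recovery_and_handoff(self, mini_noiseless_study):
        ana = KissingerAnalysis(mini_noiseless_study)
        results = ana.fit()
        # truth activation energies of the inert-atmosphere fixture
        truth = {1: 140e3, 2: 165e3, 3: 195e3}
        for step, E_true in truth.items():
            res = results[("n2", step)]
            assert res.mode == "linear"
            assert abs(res.E - E_true) / E_true < 0.03
        c10 = [c for c in mini_noiseless_study if c.q_plus == 10][0]
        fixed = results.fixed_E_for_curve(c10)
        assert len(fixed) == 3
        assert all(abs(E - truth[i + 1]) / truth[i + 1] < 0.03 for i, E in enumerate(fixed))

    def test_peak_table_monotone_in_rate(self, mini_noiseless_study):
        ana = KissingerAnalysis(mini_noiseless_study)
        peaks = ana.peaks
        for step, grp in peaks.groupby("step_index"):
            tp = grp.sort_values("q_plus")["Tp_K"].to_numpy()
            assert np.all(np.diff(tp) > 0)
        # step ordering at each rate
        for q, grp in peaks.groupby("q_plus"):
            tp = grp.sort_values("step_index")["Tp_K"].to_numpy()
            assert np.all(np.diff(tp) > 0)
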