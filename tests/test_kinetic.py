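"""Rate law, consecutive ODE system, integration and serialization."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rk4_integrate, single_step_model, smooth_three_step_toy, three_step_toy
from tgakinetics.kinetic import (
    GAS_CONSTANT,
    ActivationEnergy,
    ConsecutiveModel,
    StepKinetics,
    arrhenius_rate_constant,
    conversion_from_mass,
    integrate,
    model_from_json,
    model_to_json,
    observed_mass,
    ode_rhs,
    relative_mass,
    sestak_berggren,
)
from tgakinetics.programs import (
    celsius_to_kelvin,
    make_isothermal,
    make_linear_ramp,
    rate_per_min_to_per_s,
)


class TestSestakBerggren:
    @pytest.mark.parametrize(
        "alpha,M,N,expected",
        [
            (0.5, 1, 1, 0.25),
            (0.0, 0.5, 2, 0.0),
            (1.0, 0.5, 2, 0.0),
            (0.5, 0, 1, 0.5),
        ],
    )
    def test_values(self, alpha, M, N, expected):
        assert sestak_berggren(alpha, M, N) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_domain(self, alpha):
        with pytest.raises(ValueError):
            sestak_berggren(alpha, 1, 1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.floats(0, 1),
        M=st.floats(0.01, 3),
        N=st.floats(0.05, 6),
    )
    def test_nonnegative_and_bounded(self, a, M, N):
        v = sestak_berggren(a, M, N)
        assert 0 <= v <= 1


class TestArrhenius:
    def test_zero_activation_energy_gives_A(self):
        step = StepKinetics(E=ActivationEnergy.constant(0.0), A=5e10, M=0.5, N=1)
        assert arrhenius_rate_constant(step, 400.0) == pytest.approx(5e10)

    def test_scalar_evaluation(self):
        # independent direct evaluation of A*exp(-E/RT)
        step = StepKinetics(E=ActivationEnergy.constant(100000.0), A=1e10, M=0.5, N=1)
        expected = 1e10 * math.exp(-100000.0 / (8.314 * 500.0))
        assert arrhenius_rate_constant(step, 500.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_temperature_rejected(self):
        step = StepKinetics(E=ActivationEnergy.constant(150000.0), A=1e12, M=0.5, N=1)
        with pytest.raises(ValueError):
            arrhenius_rate_constant(step, -10.0)

    def test_monotone_in_temperature(self):
        step = StepKinetics(E=ActivationEnergy.constant(150000.0), A=1e12, M=0.5, N=1)
        ks = [arrhenius_rate_constant(step, T) for T in (400, 450, 500, 550)]
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))

    def test_temperature_dependent_window(self):
        E = ActivationEnergy.from_kissinger_quadratic(b=-15000.0, c=-1e6, T_min=450.0, T_max=550.0)
        step = StepKinetics(E=E, A=1e10, M=0.5, N=1)
        arrhenius_rate_constant(step, 500.0)
        with pytest.raises(ValueError):
            arrhenius_rate_constant(step, 600.0)
        # explicit clamping evaluates at the window edge
        assert arrhenius_rate_constant(step, 600.0, clamp_E=True) == pytest.approx(
            step.A * math.exp(-E.value_at(550.0) / (GAS_CONSTANT * 600.0))
        )


class TestConversionFromMass:
    @pytest.mark.parametrize("m,m0,expected", [(1.0, 1.0, 0.0), (0.0, 1.0, 1.0), (4.0, 5.0, 0.2)])
    def test_values(self, m, m0, expected):
        assert conversion_from_mass(m, m0) == pytest.approx(expected)

    def test_mass_gain_rejected(self):
        with pytest.raises(ValueError):
            conversion_from_mass(1.1, 1.0)


class TestMassReconstruction:
    def test_relative_mass_endpoints(self):
        assert relative_mass(1, 0, 0, 0, 0.3, 0.5) == 0.0
        assert relative_mass(0, 0, 0, 1, 0.3, 0.5) == 1.0

    def test_relative_mass_first_step_complete(self):
        assert relative_mass(0, 1, 0, 0, 0.13, 0.5) == pytest.approx(0.13)

    @pytest.mark.parametrize(
        "m_rel,expected", [(0.0, 1.0), (1.0, 0.10), (0.5, 0.55)]
    )
    def test_observed_mass(self, m_rel, expected):
        assert observed_mass(m_rel, 1.0, -0.9) == pytest.approx(expected)


class TestOdeRhs:
    def test_unseeded_initial_state_is_locked(self):
        # product-catalyzed rates vanish with zero product present
        model = three_step_toy()
        prog = make_isothermal(600.0, 100.0)
        d = ode_rhs((1.0, 0.0, 0.0), 0.0, model, prog)
        assert d == (0.0, 0.0, 0.0)

    def test_balance_identity(self):
        model = three_step_toy()
        prog = make_isothermal(600.0, 100.0)
        for state in [(0.5, 0.3, 0.1), (0.2, 0.2, 0.2), (0.9, 0.05, 0.04)]:
            dA, dB, dC = ode_rhs(state, 10.0, model, prog)
            dD = -(dA + dB + dC)  # rate of the third transition
            assert dA + dB + dC + dD == pytest.approx(0.0, abs=1e-30)
            assert dA <= 0

    def test_hand_substitution(self):
        # dm_A/dt = -k1 * mB^M1 * (1-mB)^N1 with M1 = N1 = 1 and mB = 0.5
        E, A = 120e3, 1e10
        step1 = StepKinetics(E=ActivationEnergy.constant(E), A=A, M=1.0, N=1.0)
        off = StepKinetics(E=ActivationEnergy.constant(E), A=0.0, M=0.5, N=1.0)
        model = ConsecutiveModel(steps=(step1, off, off), w1=1.0, w2=0.0, delta_m=-1.0)
        T = 600.0
        prog = make_isothermal(T, 100.0)
        k1 = A * math.exp(-E / (GAS_CONSTANT * T))
        dA, dB, dC = ode_rhs((0.5, 0.5, 0.0), 0.0, model, prog)
        assert dA == pytest.approx(-k1 * 0.25, rel=1e-12)


class TestIntegrate:
    def test_first_order_closed_form(self):
        # single step, M=0, N=1, isothermal: alpha(t) = 1 - exp(-k t)
        E, A, T = 150e3, 1e12, 520.0
        model = single_step_model(E=E, A=A, M=0.0, N=1.0)
        k = A * math.exp(-E / (GAS_CONSTANT * T))
        t_half = math.log(2) / k
        grid = np.linspace(0, 5 * t_half, 400)
        prog = make_isothermal(T, grid[-1] * 1.01)
        traj = integrate(model, prog, grid)
        expected = 1.0 - np.exp(-k * grid)
        assert np.max(np.abs(traj.m_rel - expected)) < 1e-6

    def test_conservation_random_models(self):
        rng = np.random.default_rng(7)
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(10)
        )
        grid = prog.time_grid(n=200)
        for _ in range(10):
            steps = tuple(
                StepKinetics(
                    E=ActivationEnergy.constant(rng.uniform(80e3, 250e3)),
                    A=10.0 ** rng.uniform(6, 16),
                    M=rng.uniform(0, 1.5),
                    N=rng.uniform(0.5, 6),
                )
                for _ in range(3)
            )
            w1 = rng.uniform(0, 0.5)
            w2 = rng.uniform(0, 1 - w1)
            model = ConsecutiveModel(steps=steps, w1=w1, w2=w2, delta_m=-0.9)
            traj = integrate(model, prog, grid)
            assert traj.conservation_error() < 1e-8

    def test_monotonicity_under_heating(self):
        from tgakinetics.synthetic import n2_like_model

        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(5)
        )
        traj = integrate(n2_like_model(), prog, prog.time_grid(n=500))
        tol = 1e-10
        assert np.all(np.diff(traj.m_A) <= tol)
        assert np.all(np.diff(traj.m_D) >= -tol)
        assert np.all(np.diff(traj.m_rel) >= -tol)

    def test_rk4_oracle_equivalence(self):
        # adaptive solver vs independent fixed-step integrator, 100 s window
        model = smooth_three_step_toy()
        prog = make_isothermal(640.0, 100.0)
        grid = np.linspace(0, 100.0, 101)
        traj = integrate(model, prog, grid, rtol=1e-10, atol=1e-13)
        *_, m_rel_oracle = rk4_integrate(model, prog, grid, substep=0.01)
        assert np.max(np.abs(traj.m_rel - m_rel_oracle)) < 1e-6

    def test_seed_eps_insensitivity(self):
        model = three_step_toy()
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(10)
        )
        grid = prog.time_grid(n=300)
        a = integrate(model.with_seed_eps(1e-8), prog, grid)
        b = integrate(model.with_seed_eps(5e-9), prog, grid)
        assert np.max(np.abs(a.m_rel - b.m_rel)) < 1e-4

    def test_step_conversion_mode_differs_but_conserves(self):
        # the alternative conversion-variable reading changes the dynamics
        # yet keeps the balance closed and the signal monotone
        model = three_step_toy()
        alt = __import__("dataclasses").replace(model, conversion_mode="step_conversion")
        prog = make_linear_ramp(
            celsius_to_kelvin(30), celsius_to_kelvin(550), rate_per_min_to_per_s(10)
        )
        grid = prog.time_grid(n=300)
        a = integrate(model, prog, grid)
        b = integrate(alt, prog, grid)
        assert b.conservation_error() < 1e-8
        assert np.all(np.diff(b.m_rel) >= -1e-10)
        assert np.max(np.abs(a.m_rel - b.m_rel)) > 1e-3

    def test_decreasing_grid_rejected(self):
        model = three_step_toy()
        prog = make_isothermal(600.0, 100.0)
        with pytest.raises(ValueError):
            integrate(model, prog, np.array([0.0, 50.0, 40.0]))


class TestSerialization:
    def test_round_trip_is_identity(self):
        model = three_step_toy()
        doc1 = model_to_json(model)
        doc2 = model_to_json(model_from_json(doc1))
        assert doc1 == doc2

    def test_temperature_dependent_round_trip(self):
        E = ActivationEnergy.from_kissinger_quadratic(b=-17000.0, c=-8e5, T_min=450.0, T_max=560.0)
        step = StepKinetics(E=E, A=1e11, M=0.4, N=1.5)
        off = StepKinetics(E=ActivationEnergy.constant(150e3), A=0.0, M=0.5, N=1.0)
        model = ConsecutiveModel(steps=(step, off, off), w1=1.0, w2=0.0, delta_m=-0.8)
        doc1 = model_to_json(model)
        restored = model_from_json(doc1)
        assert restored.steps[0].E.mode == "temperature_dependent"
        assert model_to_json(restored) == doc1

    def test_fields_survive(self):
        model = three_step_toy()
        restored = model_from_json(model_to_json(model))
        assert restored.w1 == model.w1
        assert restored.delta_m == model.delta_m
        for s1, s2 in zip(model.steps, restored.steps):
            assert s2.M == s1.M and s2.N == s1.N
            assert math.isclose(s2.A, s1.A, rel_tol=1e-12)
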