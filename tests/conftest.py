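"""Shared fixtures: reduced models, small synthetic studies, an RK4 oracle."""

import numpy as np
import pytest

from tgakinetics.kinetic import (
    ActivationEnergy,
    ConsecutiveModel,
    StepKinetics,
)
from tgakinetics.synthetic import NoiseSpec, StudyDesign, generate_study, n2_like_model


def single_step_model(E=150e3, A=1e12, M=0.3, N=1.2, delta_m=-1.0):
    """Reduced model: only step 1 active (steps 2-3 rates forced to zero),
    all mass loss in the first step (w1 = 1)."""
    off = StepKinetics(E=ActivationEnergy.constant(E), A=0.0, M=0.5, N=1.0)
    return ConsecutiveModel(
        steps=(StepKinetics(E=ActivationEnergy.constant(E), A=A, M=M, N=N), off, off),
        w1=1.0,
        w2=0.0,
        delta_m=delta_m,
    )


def three_step_toy():
    """Small consecutive model with overlapping steps, used as an ODE test case."""
    return ConsecutiveModel(
        steps=(
            StepKinetics(E=ActivationEnergy.constant(120e3), A=1e10, M=0.4, N=1.2),
            StepKinetics(E=ActivationEnergy.constant(140e3), A=1e11, M=0.5, N=1.5),
            StepKinetics(E=ActivationEnergy.constant(160e3), A=1e12, M=0.6, N=2.0),
        ),
        w1=0.2,
        w2=0.5,
        delta_m=-0.85,
    )


def smooth_three_step_toy():
    """Consecutive toy with M = 1 steps (smooth escape from the seeded
    start), suitable for cross-checking against a fixed-step integrator."""
    return ConsecutiveModel(
        steps=(
            StepKinetics(E=ActivationEnergy.constant(120e3), A=1e10, M=1.0, N=1.2),
            StepKinetics(E=ActivationEnergy.constant(140e3), A=1e11, M=1.0, N=1.5),
            StepKinetics(E=ActivationEnergy.constant(160e3), A=1e12, M=1.0, N=2.0),
        ),
        w1=0.2,
        w2=0.5,
        delta_m=-0.85,
    )


def rk4_integrate(model, program, t_grid, substep=0.01):
    """Independent fixed-step fourth-order Runge-Kutta oracle.

    Implements the consecutive balance equations directly (product-species
    autocatalytic rates, source-availability gating, algebraic m_D) without
    touching the package's adaptive solver.
    """
    R = 8.314
    gate_w = 1e-6

    def rates(t, y):
        mA, mB, mC = y
        mD = 1.0 - mA - mB - mC
        T = program.temperature_at(float(t))
        out = []
        for step, x, src in zip(model.steps, (mB, mC, mD), (mA, mB, mC)):
            if step.A == 0:
                out.append(0.0)
                continue
            xc = min(max(x, 0.0), 1.0)
            f = (1.0 if step.M == 0 else xc**step.M) * (1.0 - xc) ** step.N
            if xc <= 0.0 and step.M > 0:
                f = 0.0
            g = min(max(src / gate_w, 0.0), 1.0)
            out.append(step.A * np.exp(-step.E.E0 / (R * T)) * f * g)
        r1, r2, r3 = out
        return np.array([-r1, r1 - r2, r2 - r3])

    eps = model.seed_eps
    y = np.array([1.0 - 3.0 * eps, eps, eps])
    t_grid = np.asarray(t_grid, dtype=float)
    ys = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        n = max(int(np.ceil((t1 - t0) / substep)), 1)
        h = (t1 - t0) / n
        t = t0
        for _ in range(n):
            k1 = rates(t, y)
            k2 = rates(t + h / 2, y + h / 2 * k1)
            k3 = rates(t + h / 2, y + h / 2 * k2)
            k4 = rates(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        ys.append(y.copy())
    ys = np.array(ys)
    mA, mB, mC = ys.T
    mD = 1.0 - mA - mB - mC
    m_rel = model.w1 * (1 - mA) + model.w2 * (mC + mD) + (1 - model.w1 - model.w2) * mD
    return mA, mB, mC, mD, m_rel


@pytest.fixture(scope="session")
def mini_noiseless_study():
    """Noiseless single-atmosphere study at six heating rates (session-wide)."""
    design = StudyDesign(
        q_list=(0.5, 1, 2, 5, 10, 20),
        atmosphere_models={"n2": n2_like_model()},
        sampling_interval=2.0,
    )
    return generate_study(design, NoiseSpec.noiseless())


@pytest.fixture(scope="session")
def noisy_curve_q10():
    """One noisy 10 degC/min curve from the inert-atmosphere truth model."""
    design = StudyDesign(
        q_list=(10,), atmosphere_models={"n2": n2_like_model()}, sampling_interval=1.0
    )
    return generate_study(design, NoiseSpec(seed=42))[0]
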