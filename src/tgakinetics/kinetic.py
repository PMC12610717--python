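"""Consecutive three-step autocatalytic decomposition kinetics.

The decomposition A -> B -> C -> D is described by normalized state masses
``m_A..m_D`` (summing to one) with each transition following an Arrhenius
rate constant ``k_x(T) = A_x * exp(-E_x / (R T))`` and the two-exponent
Sestak-Berggren (autocatalytic) conversion function
``f(x) = x**M * (1 - x)**N`` evaluated on the *product* species of that
transition:

    dm_A/dt = -k1(T) * f(m_B; M1, N1)
    dm_B/dt = +k1(T) * f(m_B; M1, N1) - k2(T) * f(m_C; M2, N2)
    dm_C/dt = +k2(T) * f(m_C; M2, N2) - k3(T) * f(m_D; M3, N3)
    m_D     = 1 - m_A - m_B - m_C

The measurable signal is reconstructed from the state by

    m_rel = w1 * (1 - m_A) + w2 * (m_C + m_D) + (1 - w1 - w2) * m_D
    m     = m(t=0) + delta_m * m_rel

where ``w1``/``w2`` are the fractional contributions of the first two mass
loss steps and ``delta_m`` the total (signed) relative mass change.

Because the rates are catalyzed by the product species, the exact state
(1, 0, 0, 0) is a fixed point; integration therefore seeds each product
species with a tiny amount ``seed_eps`` (insensitivity to its value is part
of the test suite).  Each rate is additionally gated by the availability of
its source species so that no state mass can be driven negative once its
source is exhausted; the gate is inactive whenever all species are
positive, leaving the rate law above unchanged.

Activation energies may be constant or temperature dependent.  The
temperature-dependent form arises from a quadratic fit of the Kissinger
plot y = a + b*x + c*x**2 in x = 1/Tp, whose derivative gives
``E(T) = -R * (b + 2*c/T)`` over the fitted temperature window.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from .programs import HeatingProgram, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "GAS_CONSTANT",
    "ActivationEnergy",
    "StepKinetics",
    "ConsecutiveModel",
    "StateTrajectory",
    "IntegrationError",
    "sestak_berggren",
    "arrhenius_rate_constant",
    "conversion_from_mass",
    "ode_rhs",
    "integrate",
    "relative_mass",
    "observed_mass",
    "model_to_json",
    "model_from_json",
]

logger = logging.getLogger(__name__)

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries solver diagnostics."""


@dataclass(frozen=True)
class ActivationEnergy:
    """Constant or temperature-dependent activation energy (J/mol).

    ``mode="constant"`` uses ``E0``.  ``mode="temperature_dependent"``
    evaluates ``E(T) = -R * (b + 2*c/T)`` inside the validity window
    ``(T_min, T_max)`` in kelvin; outside the window evaluation either
    raises or clamps to the window edge, at the caller's choice.
    """

    mode: str = "constant"
    E0: float = 0.0
    b: float = 0.0
    c: float = 0.0
    T_min: float = 0.0
    T_max: float = float("inf")

    def __post_init__(self):
        if self.mode == "constant":
            if not np.isfinite(self.E0) or self.E0 < 0:
                raise ValueError("constant activation energy must be finite and >= 0")
        elif self.mode == "temperature_dependent":
            if not (self.T_min > 0 and self.T_max > self.T_min):
                raise ValueError("temperature_dependent mode needs a valid kelvin window")
        else:
            raise ValueError(f"unknown activation-energy mode {self.mode!r}")

    def value_at(self, T: float, clamp: bool = False) -> float:
        """E(T) in J/mol at absolute temperature T."""
        if self.mode == "constant":
            return self.E0
        if T < self.T_min or T > self.T_max:
            if not clamp:
                raise ValueError(
                    f"T={T:.2f} K outside E(T) validity window "
                    f"[{self.T_min:.2f}, {self.T_max:.2f}] K"
                )
            T = min(max(T, self.T_min), self.T_max)
        return -GAS_CONSTANT * (self.b + 2.0 * self.c / T)

    @staticmethod
    def constant(E0: float) -> "ActivationEnergy":
        return ActivationEnergy(mode="constant", E0=E0)

    @staticmethod
    def from_kissinger_quadratic(b: float, c: float, T_min: float, T_max: float) -> "ActivationEnergy":
        return ActivationEnergy(
            mode="temperature_dependent", b=b, c=c, T_min=T_min, T_max=T_max
        )


@dataclass(frozen=True)
class StepKinetics:
    """Arrhenius + Sestak-Berggren parameters of one decomposition step.

    ``A = 0`` disables the step (used for reduced single-step models).
    """

    E: ActivationEnergy
    A: float  # pre-exponential constant, 1/s
    M: float  # first autocatalytic exponent, >= 0
    N: float  # second autocatalytic exponent, > 0

    def __post_init__(self):
        if self.A < 0:
            raise ValueError("pre-exponential constant must be >= 0")
        if self.M < 0:
            raise ValueError("exponent M must be >= 0")
        if self.N <= 0:
            raise ValueError("exponent N must be > 0")


@dataclass(frozen=True)
class ConsecutiveModel:
    """Three consecutive steps plus the mass-balance bookkeeping.

    ``conversion_mode`` selects the conversion variable fed to each step's
    Sestak-Berggren function: ``"product_species"`` (default) uses the raw
    product amounts m_B, m_C, m_D as written in the balance equations;
    ``"step_conversion"`` uses per-step normalized conversions
    alpha_1 = 1 - m_A, alpha_2 = (m_C + m_D)/(1 - m_A), alpha_3 =
    m_D/(m_C + m_D) -- a common alternative reading of autocatalytic
    kinetics in consecutive schemes.
    """

    steps: tuple[StepKinetics, StepKinetics, StepKinetics]
    w1: float
    w2: float
    delta_m: float  # signed total relative mass change (negative for loss)
    m_t0: float = 1.0
    seed_eps: float = 1e-8
    conversion_mode: str = "product_species"

    def __post_init__(self):
        if len(self.steps) != 3:
            raise ValueError("exactly three steps required")
        if self.conversion_mode not in ("product_species", "step_conversion"):
            raise ValueError(f"unknown conversion_mode {self.conversion_mode!r}")
        object.__setattr__(self, "steps", tuple(self.steps))
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 > 1 + 1e-12:
            raise ValueError("weights must satisfy w1, w2 >= 0 and w1 + w2 <= 1")
        if abs(self.delta_m) > 1:
            raise ValueError("|delta_m| must be <= 1")
        if not (0 < self.seed_eps <= 1e-4):
            raise ValueError("seed_eps must be in (0, 1e-4]")

    @property
    def w3(self) -> float:
        return 1.0 - self.w1 - self.w2

    def with_seed_eps(self, seed_eps: float) -> "ConsecutiveModel":
        return replace(self, seed_eps=seed_eps)


@dataclass(frozen=True)
class StateTrajectory:
    """Time-resolved solution of the consecutive model."""

    t: np.ndarray
    T: np.ndarray
    m_A: np.ndarray
    m_B: np.ndarray
    m_C: np.ndarray
    m_D: np.ndarray
    m_rel: np.ndarray
    m: np.ndarray
    clamped_E: bool = False

    @property
    def T_C(self) -> np.ndarray:
        return kelvin_to_celsius(self.T)

    @property
    def conversion(self) -> np.ndarray:
        """Total-mass-loss-normalized degree of conversion (= m_rel)."""
        return self.m_rel

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.m_A + self.m_B + self.m_C + self.m_D - 1.0)))


def sestak_berggren(alpha, M: float, N: float):
    """Autocatalytic model function f(alpha) = alpha**M * (1-alpha)**N."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    out = a**M * (1.0 - a) ** N
    return out if np.ndim(alpha) else float(out)


def arrhenius_rate_constant(step: StepKinetics, T: float, clamp_E: bool = False) -> float:
    """k(T) = A * exp(-E(T) / (R T)) in 1/s."""
    if T <= 0:
        raise ValueError("absolute temperature must be > 0")
    E = step.E.value_at(T, clamp=clamp_E)
    return step.A * math.exp(-E / (GAS_CONSTANT * T))


def conversion_from_mass(m, m0: float, tol: float = 1e-6):
    """Degree of conversion alpha = (m0 - m)/m0 from mass-loss data."""
    if m0 <= 0:
        raise ValueError("m0 must be > 0")
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr > m0 * (1 + tol)):
        raise ValueError("mass exceeds initial mass; mass gain is not modeled")
    alpha = np.clip((m0 - m_arr) / m0, 0.0, 1.0)
    return alpha if np.ndim(m) else float(alpha)


def relative_mass(m_A, m_B, m_C, m_D, w1: float, w2: float):
    """Signal reconstruction m_rel = w1(1-m_A) + w2(m_C+m_D) + (1-w1-w2) m_D."""
    return w1 * (1.0 - m_A) + w2 * (m_C + m_D) + (1.0 - w1 - w2) * m_D


def observed_mass(m_rel, m_t0: float, delta_m: float):
    """Observable relative mass m = m(t=0) + delta_m * m_rel."""
    return m_t0 + delta_m * m_rel


# width of the source-availability gate; rates are unchanged for source > gate.
# Narrower gates make the exhaustion kink needlessly stiff for the solver.
_GATE = 1e-6


def _gate(x: float) -> float:
    if x <= 0.0:
        return 0.0
    if x >= _GATE:
        return 1.0
    return x / _GATE


def _sb(x: float, M: float, N: float) -> float:
    if x <= 0.0:
        return 1.0 if M == 0 else 0.0
    if x >= 1.0:
        return 0.0
    return x**M * (1.0 - x) ** N


def _make_rhs(model: ConsecutiveModel, program: HeatingProgram, clamp_E: bool):
    """Build a fast scalar RHS closure for the (m_A, m_B, m_C) system."""
    s1, s2, s3 = model.steps
    R = GAS_CONSTANT

    # flatten segment geometry for a cheap scalar T(t)
    seg_t0, seg_T0, seg_rate = [], [], []
    start = 0.0
    for seg in program.segments:
        seg_t0.append(start)
        seg_T0.append(seg.start_temperature)
        seg_rate.append(seg.rate if seg.kind == "ramp" else 0.0)
        start += seg.duration
    seg_t1 = [t0 + seg.duration for t0, seg in zip(seg_t0, program.segments)]
    nseg = len(seg_t0)

    clamp_hits = [0]

    def E_of(step: StepKinetics, T: float) -> float:
        e = step.E
        if e.mode == "constant":
            return e.E0
        Tc = T
        if Tc < e.T_min or Tc > e.T_max:
            if not clamp_E:
                raise ValueError("temperature outside E(T) validity window")
            clamp_hits[0] += 1
            Tc = e.T_min if Tc < e.T_min else e.T_max
        return -R * (e.b + 2.0 * e.c / Tc)

    def T_of(t: float) -> float:
        for i in range(nseg):
            if t <= seg_t1[i] or i == nseg - 1:
                return seg_T0[i] + seg_rate[i] * (t - seg_t0[i])
        return seg_T0[-1]  # pragma: no cover

    step_conv = model.conversion_mode == "step_conversion"
    tiny = 1e-12

    def rhs(t, y):
        mA, mB, mC = y
        mD = 1.0 - mA - mB - mC
        T = T_of(t)
        inv_RT = 1.0 / (R * T)
        if step_conv:
            a1 = 1.0 - mA
            a2 = (mC + mD) / (1.0 - mA + tiny)
            a3 = mD / (mC + mD + tiny)
        else:
            a1, a2, a3 = mB, mC, mD
        r1 = s1.A * math.exp(-E_of(s1, T) * inv_RT) * _sb(a1, s1.M, s1.N) * _gate(mA) if s1.A else 0.0
        r2 = s2.A * math.exp(-E_of(s2, T) * inv_RT) * _sb(a2, s2.M, s2.N) * _gate(mB) if s2.A else 0.0
        r3 = s3.A * math.exp(-E_of(s3, T) * inv_RT) * _sb(a3, s3.M, s3.N) * _gate(mC) if s3.A else 0.0
        return (-r1, r1 - r2, r2 - r3)

    return rhs, clamp_hits


def ode_rhs(state, t: float, model: ConsecutiveModel, program: HeatingProgram):
    """Time derivatives (dm_A/dt, dm_B/dt, dm_C/dt) of the balance equations.

    The fourth derivative dm_D/dt equals -(sum of the three returned), i.e.
    the rate of the third transition; m_D itself is recovered algebraically
    as 1 - m_A - m_B - m_C so that conservation holds exactly.
    """
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    rhs, _ = _make_rhs(model, program, clamp_E=True)
    return rhs(t, tuple(float(x) for x in state))


def integrate(
    model: ConsecutiveModel,
    program: HeatingProgram,
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateTrajectory:
    """Integrate the consecutive model under a thermal program.

    Initial condition: each product species (B, C and, through the algebraic
    closure, D) is seeded with ``model.seed_eps`` so the product-catalyzed
    rates can start; ``m_A = 1 - 3*seed_eps``.

    Temperature-dependent activation energies are clamped to their validity
    window edge during integration (a warning is logged and the trajectory
    flags it).
    """
    if output_grid is None:
        output_grid = program.time_grid(n=1000)
    t_eval = np.asarray(output_grid, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) < 2 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("output_grid must be strictly increasing with >= 2 points")
    total = program.total_duration
    if t_eval[0] < -1e-9 or t_eval[-1] > total * (1 + 1e-12) + 1e-9:
        raise ValueError("output_grid must lie within the program duration")

    eps = model.seed_eps
    y0 = (1.0 - 3.0 * eps, eps, eps)
    rhs, clamp_hits = _make_rhs(model, program, clamp_E=True)

    # LSODA via the low-overhead odeint loop (stiff-capable, adaptive)
    y, info = odeint(
        rhs,
        y0,
        t_eval,
        rtol=rtol,
        atol=atol,
        tfirst=True,
        full_output=True,
        printmessg=False,
        mxstep=100_000,
    )
    if info.get("message") != "Integration successful.":
        raise IntegrationError(f"ODE solver failed: {info.get('message')}")
    mA, mB, mC = y.T
    mA = np.clip(mA, 0.0, 1.0)
    mB = np.clip(mB, 0.0, 1.0)
    mC = np.clip(mC, 0.0, 1.0)
    mD = np.clip(1.0 - mA - mB - mC, 0.0, 1.0)
    m_rel = np.clip(relative_mass(mA, mB, mC, mD, model.w1, model.w2), 0.0, 1.0)
    m = observed_mass(m_rel, model.m_t0, model.delta_m)
    T = np.asarray(program.temperature_at(t_eval), dtype=float)
    if clamp_hits[0]:
        logger.warning(
            "E(T) clamped to validity-window edge at %d RHS evaluations", clamp_hits[0]
        )
    return StateTrajectory(
        t=t_eval, T=T, m_A=mA, m_B=mB, m_C=mC, m_D=mD, m_rel=m_rel, m=m,
        clamped_E=bool(clamp_hits[0]),
    )


# ---------------------------------------------------------------------------
# serialization


def _step_to_dict(step: StepKinetics) -> dict:
    d: dict = {}
    if step.E.mode == "constant":
        d["E_kJ_mol"] = step.E.E0 / 1000.0
    else:
        d["E_poly"] = {
            "b": step.E.b,
            "c": step.E.c,
            "T_min_C": kelvin_to_celsius(step.E.T_min),
            "T_max_C": kelvin_to_celsius(step.E.T_max),
        }
    d["log10_A_per_s"] = math.log10(step.A) if step.A > 0 else None
    d["M"] = step.M
    d["N"] = step.N
    return d


def _step_from_dict(d: dict) -> StepKinetics:
    if "E_poly" in d:
        p = d["E_poly"]
        E = ActivationEnergy.from_kissinger_quadratic(
            p["b"], p["c"], celsius_to_kelvin(p["T_min_C"]), celsius_to_kelvin(p["T_max_C"])
        )
    else:
        E = ActivationEnergy.constant(d["E_kJ_mol"] * 1000.0)
    log10A = d["log10_A_per_s"]
    A = 0.0 if log10A is None else 10.0**log10A
    return StepKinetics(E=E, A=A, M=d["M"], N=d["N"])


def model_to_json(model: ConsecutiveModel) -> str:
    """Serialize to the canonical JSON document (bit-exact round trip)."""
    doc = {
        "steps": [_step_to_dict(s) for s in model.steps],
        "w1": model.w1,
        "w2": model.w2,
        "delta_m": model.delta_m,
        "m_t0": model.m_t0,
        "seed_eps": model.seed_eps,
    }
    if model.conversion_mode != "product_species":
        doc["conversion_mode"] = model.conversion_mode
    return json.dumps(doc, indent=2, sort_keys=True)


def model_from_json(text: str) -> ConsecutiveModel:
    doc = json.loads(text)
    steps = tuple(_step_from_dict(d) for d in doc["steps"])
    return ConsecutiveModel(
        steps=steps,
        w1=doc["w1"],
        w2=doc["w2"],
        delta_m=doc["delta_m"],
        m_t0=doc.get("m_t0", 1.0),
        seed_eps=doc.get("seed_eps", 1e-8),
        conversion_mode=doc.get("conversion_mode", "product_species"),
    )
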