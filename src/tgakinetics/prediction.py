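"""Extrapolation of fitted kinetics to processing-relevant protocols.

Predicts isothermal annealing (with or without a preceding heating ramp,
as in hot-melt extrusion / fused-deposition-modeling exposure scenarios),
reports conversion and mass-loss trajectories on a clock starting at the
hold onset, and summarizes times to reach threshold conversions.

Conversion here is total-mass-loss-normalized (alpha == m_rel); the
corresponding "% mass loss" is |delta_m| * alpha * 100 for models carrying
a total mass change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetic import ConsecutiveModel, integrate
from .programs import make_isothermal, make_ramp_hold

__all__ = [
    "PredictionProtocol",
    "PredictionResult",
    "predict",
    "time_to_conversion",
    "compare_bases",
    "DEFAULT_REPORT_TIMES",
]

#: report times (s) used by the basis-comparison table
DEFAULT_REPORT_TIMES = (30.0, 60.0, 300.0, 900.0, 3600.0)


@dataclass(frozen=True)
class PredictionProtocol:
    """Isothermal hold, optionally preceded by a heating ramp.

    hold_temperature : kelvin
    hold_duration : seconds
    ramp : optional (start_temperature_K, rate_K_per_s) for the preceding
        heating step; omitted -> annealing starts directly at the hold
        temperature.
    resolution : output grid spacing during the hold, seconds
    """

    hold_temperature: float
    hold_duration: float
    ramp: tuple[float, float] | None = None
    resolution: float = 1.0

    def __post_init__(self):
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be > 0")
        if self.ramp is not None:
            start_T, rate = self.ramp
            if start_T >= self.hold_temperature:
                raise ValueError("ramp start temperature must be below the hold temperature")
            if rate <= 0:
                raise ValueError("ramp rate must be > 0")

    def program(self):
        if self.ramp is None:
            return make_isothermal(self.hold_temperature, self.hold_duration), 0.0
        start_T, rate = self.ramp
        prog = make_ramp_hold(start_T, self.hold_temperature, rate, self.hold_duration)
        ramp_duration = prog.total_duration - self.hold_duration
        return prog, ramp_duration


@dataclass(frozen=True)
class PredictionResult:
    """Conversion/mass trajectory on the hold clock.

    ``t_hold`` starts at the hold onset; ``pre_conversion`` is the
    conversion already accumulated during the preceding ramp (0 without a
    ramp).  ``time_to_thresholds`` maps threshold conversion fractions to
    the first crossing time on the hold clock, or None when not reached
    within the hold.
    """

    t_hold: np.ndarray
    T: np.ndarray
    conversion: np.ndarray
    mass_loss_pct: np.ndarray
    m: np.ndarray
    pre_conversion: float
    time_to_thresholds: dict
    provenance: dict = field(default_factory=dict)
    clamped_E: bool = False


def predict(
    model: ConsecutiveModel,
    protocol: PredictionProtocol,
    thresholds=(0.01,),
    provenance: dict | None = None,
) -> PredictionResult:
    """Integrate the model under the protocol and summarize threshold times.

    Temperature-dependent activation energies are clamped at their validity
    window edges during extrapolation (flagged on the result).
    """
    prog, ramp_duration = protocol.program()
    n_hold = max(int(np.ceil(protocol.hold_duration / protocol.resolution)) + 1, 2)
    hold_grid = ramp_duration + np.linspace(0.0, protocol.hold_duration, n_hold)
    if ramp_duration > 0:
        n_ramp = min(max(int(ramp_duration / protocol.resolution), 2), 2000)
        grid = np.concatenate([np.linspace(0.0, ramp_duration, n_ramp, endpoint=False), hold_grid])
    else:
        grid = hold_grid
    traj = integrate(model, prog, grid)

    on_hold = grid >= ramp_duration - 1e-12
    t_hold = grid[on_hold] - ramp_duration
    alpha = traj.m_rel[on_hold]
    pre = float(alpha[0])
    ttt = {float(th): _first_crossing(t_hold, alpha, th) for th in thresholds}
    return PredictionResult(
        t_hold=t_hold,
        T=traj.T[on_hold],
        conversion=alpha,
        mass_loss_pct=np.abs(model.delta_m) * alpha * 100.0,
        m=traj.m[on_hold],
        pre_conversion=pre,
        time_to_thresholds=ttt,
        provenance=dict(provenance or {}),
        clamped_E=traj.clamped_E,
    )


def time_to_conversion(result: PredictionResult, threshold: float):
    """First hold-clock time at which the predicted conversion crosses
    ``threshold``; None when not reached within the hold."""
    return _first_crossing(result.t_hold, result.conversion, threshold)


def _first_crossing(t, alpha, threshold: float):
    """Linear-interpolated first crossing of ``threshold``; None if absent."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    t = np.asarray(t, dtype=float)
    a = np.asarray(alpha, dtype=float)
    above = a >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or a[i] == threshold:
        return float(t[i])
    frac = (threshold - a[i - 1]) / (a[i] - a[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compare_bases(
    models: dict,
    protocols: list[PredictionProtocol],
    reference: str,
    report_times=DEFAULT_REPORT_TIMES,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Compare predictions from different kinetic parameter bases.

    One row per (basis, protocol, report time) with the conversion reached
    at that hold time, the time to the threshold conversion, and ratio
    columns against the declared reference basis.
    """
    if reference not in models:
        raise KeyError(f"unknown reference basis {reference!r}")
    if len(models) < 2:
        raise ValueError("need at least 2 bases to compare")
    preds = {}
    for label, model in models.items():
        for p_i, proto in enumerate(protocols):
            preds[(label, p_i)] = predict(model, proto, thresholds=(threshold,))
    rows = []
    for label in models:
        for p_i, proto in enumerate(protocols):
            r = preds[(label, p_i)]
            ref = preds[(reference, p_i)]
            t1 = r.time_to_thresholds[threshold]
            t1_ref = ref.time_to_thresholds[threshold]
            for rt in report_times:
                if rt > r.t_hold[-1] + 1e-9:
                    continue
                a = float(np.interp(rt, r.t_hold, r.conversion))
                a_ref = float(np.interp(rt, ref.t_hold, ref.conversion))
                rows.append(
                    {
                        "basis": label,
                        "protocol": p_i,
                        "hold_T_K": proto.hold_temperature,
                        "report_time_s": rt,
                        "conversion": a,
                        "conversion_ratio_vs_ref": a / a_ref if a_ref > 0 else np.inf if a > 0 else 1.0,
                        f"time_to_{threshold:g}_s": t1,
                        "time_ratio_vs_ref": (t1 / t1_ref) if (t1 is not None and t1_ref) else None,
                    }
                )
    return pd.DataFrame(rows)
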