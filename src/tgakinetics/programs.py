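"""Thermal protocols: linear heating ramps, isothermal holds and their combinations.

All quantities are kept in SI units internally (kelvin, seconds, K/s).
Degrees Celsius and °C/min appear only at I/O boundaries; use
:func:`celsius_to_kelvin` / :func:`rate_per_min_to_per_s` to convert once,
at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeatingSegment",
    "HeatingProgram",
    "make_linear_ramp",
    "make_ramp_hold",
    "make_isothermal",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "rate_per_min_to_per_s",
    "InvalidProgramError",
]

_ZERO_C = 273.15


def celsius_to_kelvin(T_C):
    return np.asarray(T_C, dtype=float) + _ZERO_C if np.ndim(T_C) else float(T_C) + _ZERO_C


def kelvin_to_celsius(T_K):
    return np.asarray(T_K, dtype=float) - _ZERO_C if np.ndim(T_K) else float(T_K) - _ZERO_C


def rate_per_min_to_per_s(rate_per_min: float) -> float:
    """Convert a heating rate in K/min (== °C/min) to K/s."""
    return float(rate_per_min) / 60.0


class InvalidProgramError(ValueError):
    """Raised for degenerate thermal-program specifications."""


@dataclass(frozen=True)
class HeatingSegment:
    """One piece of a thermal protocol.

    kind
        ``"ramp"`` (linear heating at ``rate`` K/s from ``start_temperature``
        to ``end_temperature``) or ``"hold"`` (constant ``start_temperature``
        for ``duration`` seconds).
    """

    kind: str
    start_temperature: float
    end_temperature: float | None = None
    rate: float | None = None
    duration: float | None = None

    def __post_init__(self):
        if self.start_temperature <= 0:
            raise InvalidProgramError("temperatures must be positive (kelvin)")
        if self.kind == "ramp":
            if self.rate is None or self.rate <= 0:
                raise InvalidProgramError("ramp rate must be > 0")
            if self.end_temperature is None or self.end_temperature <= self.start_temperature:
                raise InvalidProgramError("ramp requires end_temperature > start_temperature")
            object.__setattr__(
                self, "duration", (self.end_temperature - self.start_temperature) / self.rate
            )
        elif self.kind == "hold":
            if self.duration is None or self.duration <= 0:
                raise InvalidProgramError("hold duration must be > 0")
            object.__setattr__(self, "end_temperature", self.start_temperature)
        else:
            raise InvalidProgramError(f"unknown segment kind {self.kind!r}")

    def temperature_at(self, t_local: float) -> float:
        if self.kind == "ramp":
            return self.start_temperature + self.rate * t_local
        return self.start_temperature


@dataclass(frozen=True)
class HeatingProgram:
    """Ordered, temperature-contiguous sequence of heating segments."""

    segments: tuple[HeatingSegment, ...]
    origin_temperature: float = field(init=False)

    def __post_init__(self):
        if not self.segments:
            raise InvalidProgramError("program needs at least one segment")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for prev, nxt in zip(segs, segs[1:]):
            if abs(prev.end_temperature - nxt.start_temperature) > 1e-9:
                raise InvalidProgramError("segments must be contiguous in temperature")
        object.__setattr__(self, "origin_temperature", segs[0].start_temperature)
        if not np.isfinite(self.total_duration) or self.total_duration <= 0:
            raise InvalidProgramError("total duration must be finite and > 0")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def temperature_at(self, t):
        """Piecewise-linear temperature T(t), t in seconds from program start.

        Accepts a scalar or an array; raises for any t outside
        [0, total_duration] (no extrapolation).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        total = self.total_duration
        if np.any(t_arr < -1e-12) or np.any(t_arr > total * (1 + 1e-12) + 1e-9):
            raise ValueError(f"time outside program range [0, {total}] s")
        t_arr = np.clip(t_arr, 0.0, total)
        out = np.empty_like(t_arr)
        start = 0.0
        remaining = np.ones(t_arr.shape, dtype=bool)
        for seg in self.segments:
            end = start + seg.duration
            mask = remaining & (t_arr <= end + 1e-12)
            if mask.any():
                local = t_arr[mask] - start
                if seg.kind == "ramp":
                    out[mask] = seg.start_temperature + seg.rate * local
                else:
                    out[mask] = seg.start_temperature
                remaining &= ~mask
            start = end
        if remaining.any():  # pragma: no cover - guarded above
            out[remaining] = self.segments[-1].end_temperature
        return out if np.ndim(t) else float(out[0])

    def rate_at(self, t: float) -> float:
        """Instantaneous heating rate dT/dt (K/s) at time t."""
        start = 0.0
        for seg in self.segments:
            end = start + seg.duration
            if t <= end:
                return seg.rate if seg.kind == "ramp" else 0.0
            start = end
        return 0.0

    def time_grid(self, n: int | None = None, interval: float | None = None) -> np.ndarray:
        """Uniform output grid over [0, total_duration]."""
        total = self.total_duration
        if interval is not None:
            n = max(int(np.floor(total / interval)) + 1, 2)
        elif n is None:
            n = 1000
        return np.linspace(0.0, total, n)


def make_linear_ramp(T_start: float, T_end: float, rate: float) -> HeatingProgram:
    """Single linear heating ramp from T_start to T_end (kelvin) at ``rate`` K/s."""
    return HeatingProgram(
        (HeatingSegment("ramp", T_start, end_temperature=T_end, rate=rate),)
    )


def make_isothermal(T_hold: float, hold_duration: float) -> HeatingProgram:
    """Pure isothermal hold."""
    return HeatingProgram((HeatingSegment("hold", T_hold, duration=hold_duration),))


def make_ramp_hold(
    T_start: float, T_hold: float, rate: float, hold_duration: float
) -> HeatingProgram:
    """Ramp from T_start to T_hold then hold for ``hold_duration`` seconds.

    When ``T_hold == T_start`` the ramp collapses and a pure isothermal
    program is returned, so that annealing with and without a preceding
    heating step share one representation.
    """
    if hold_duration is None or hold_duration <= 0:
        raise InvalidProgramError("hold duration must be > 0")
    if abs(T_hold - T_start) < 1e-12:
        return make_isothermal(T_hold, hold_duration)
    if T_hold < T_start:
        raise InvalidProgramError("T_hold must be >= T_start")
    return HeatingProgram(
        (
            HeatingSegment("ramp", T_start, end_temperature=T_hold, rate=rate),
            HeatingSegment("hold", T_hold, duration=hold_duration),
        )
    )
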