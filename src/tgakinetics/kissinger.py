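"""Kissinger activation-energy analysis from mass-loss curves.

The shift of the mass-loss-rate peak temperature Tp with heating rate q
obeys ``ln(q / Tp**2) = -E / (R * Tp) + const`` for a single-step Arrhenius
process.  Plots that curve (typically at the lowest heating rates) are
instead fit with a second-order polynomial in x = 1/Tp, whose derivative
gives a temperature-dependent activation energy
``E(T) = -R * (b + 2*c / T)`` valid between the smallest and largest Tp of
the fitted points.

Workflow: :func:`mass_derivative` estimates dm/dT by local linear
regression over a fixed 2-degC window, :func:`find_step_peaks` picks the
most prominent mass-loss-rate maxima per curve, and
:class:`KissingerAnalysis` collects the per-step (q, Tp) points across a
curve set and fits them (linear or quadratic, with an F-test based mode
selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks as _scipy_find_peaks

from .curves import TGACurve
from .kinetic import GAS_CONSTANT, ActivationEnergy
from .programs import celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "DerivativeSeries",
    "PeakTable",
    "KissingerResult",
    "KissingerAnalysis",
    "PeakDetectionError",
    "mass_derivative",
    "find_step_peaks",
    "kissinger_fit",
    "kissinger_quadratic",
    "activation_energy_at",
    "select_E_mode",
]


class PeakDetectionError(RuntimeError):
    """Fewer prominent peaks than expected; carries the peaks that were found."""

    def __init__(self, message: str, found_T_C=None):
        super().__init__(message)
        self.found_T_C = [] if found_T_C is None else list(found_T_C)


@dataclass(frozen=True)
class DerivativeSeries:
    """dm/dT against temperature (window centers, degC)."""

    T_C: np.ndarray
    dm_dT: np.ndarray


def mass_derivative(curve: TGACurve, delta_T: float = 2.0) -> DerivativeSeries:
    """Estimate dm/dT by local linear regression over a [T-dT/2, T+dT/2] window.

    Robust to uneven sampling (regression, not finite differences); exact
    for data linear in T.  Requires a ramp-type curve with non-decreasing
    temperature spanning more than ``2 * delta_T``.
    """
    T = np.asarray(curve.T_C, dtype=float)
    m = np.asarray(curve.m, dtype=float)
    if np.any(np.diff(T) < 0):
        raise ValueError(
            "temperature axis is not non-decreasing; resample the curve onto a "
            "monotone temperature grid before differentiation"
        )
    span = T[-1] - T[0]
    if span <= 2 * delta_T:
        raise ValueError(f"temperature span {span:.3f} degC too small for a {delta_T} degC window")
    # coarse sampling support: the window must hold at least two points, so
    # it widens (beyond the nominal delta_T) to ~2 sampling intervals
    spacing = float(np.median(np.diff(T)))
    half = max(delta_T, 2.2 * spacing) / 2.0
    lo = np.searchsorted(T, T - half, side="left")
    hi = np.searchsorted(T, T + half, side="right")
    # keep only centers whose window fits inside the data and supports a slope
    valid = (T - half >= T[0] - 1e-12) & (T + half <= T[-1] + 1e-12) & (hi - lo >= 2)

    # windowed regression slopes via cumulative sums
    cs1 = np.concatenate(([0.0], np.cumsum(np.ones_like(T))))
    csT = np.concatenate(([0.0], np.cumsum(T)))
    csm = np.concatenate(([0.0], np.cumsum(m)))
    csTT = np.concatenate(([0.0], np.cumsum(T * T)))
    csTm = np.concatenate(([0.0], np.cumsum(T * m)))
    n = cs1[hi] - cs1[lo]
    sT = csT[hi] - csT[lo]
    sm = csm[hi] - csm[lo]
    sTT = csTT[hi] - csTT[lo]
    sTm = csTm[hi] - csTm[lo]
    denom = n * sTT - sT * sT
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (n * sTm - sT * sm) / denom, 0.0)
    return DerivativeSeries(T_C=T[valid], dm_dT=slope[valid])


def find_step_peaks(
    deriv: DerivativeSeries,
    n_steps: int = 3,
    prominence_frac: float = 0.05,
) -> list[float]:
    """Temperatures (degC) of the ``n_steps`` most prominent mass-loss-rate
    maxima (minima of dm/dT), sorted by temperature.

    ``prominence_frac`` is relative to the global maximum loss rate and
    suppresses noise-induced spurious peaks.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rate = -np.asarray(deriv.dm_dT, dtype=float)  # loss rate, positive
    top = float(np.max(rate)) if len(rate) else 0.0
    if top <= 0:
        raise PeakDetectionError("signal has no mass loss; no peaks found")
    idx, props = _scipy_find_peaks(rate, prominence=prominence_frac * top)
    if len(idx) < n_steps:
        raise PeakDetectionError(
            f"found {len(idx)} peak(s), expected {n_steps}",
            found_T_C=deriv.T_C[idx],
        )
    order = np.argsort(props["prominences"])[::-1][:n_steps]
    return sorted(float(t) for t in deriv.T_C[idx[order]])


def peak_table(
    curves: list[TGACurve],
    n_steps: int = 3,
    delta_T: float = 2.0,
    prominence_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-curve peak temperatures across a curve set.

    Columns: atmosphere, q_plus (degC/min), step_index (1..n_steps),
    Tp_K, Tp_C.
    """
    rows = []
    for c in curves:
        deriv = mass_derivative(c, delta_T=delta_T)
        tps = find_step_peaks(deriv, n_steps=n_steps, prominence_frac=prominence_frac)
        for k, tp in enumerate(tps, start=1):
            rows.append(
                {
                    "atmosphere": c.atmosphere,
                    "q_plus": c.q_plus,
                    "step_index": k,
                    "Tp_K": celsius_to_kelvin(tp),
                    "Tp_C": tp,
                }
            )
    df = pd.DataFrame(rows).sort_values(["atmosphere", "step_index", "q_plus"])
    return df.reset_index(drop=True)


#: alias matching the domain vocabulary
PeakTable = pd.DataFrame


@dataclass(frozen=True)
class KissingerResult:
    """Linear or quadratic Kissinger fit for one decomposition step.

    Linear mode: ``E`` (J/mol), ``intercept`` and ``r_squared`` of
    y = ln(q/Tp^2) vs x = 1/Tp with q in K/s.  Quadratic mode: coefficients
    (a, b, c) of y = a + b*x + c*x**2 and the kelvin validity window
    [min Tp, max Tp]; the derived activation energy is
    E(T) = -R*(b + 2c/T).
    """

    step_index: int
    mode: str
    E: float | None = None
    intercept: float | None = None
    r_squared: float = float("nan")
    a: float | None = None
    b: float | None = None
    c: float | None = None
    validity_window: tuple[float, float] | None = None

    def activation_energy(self) -> ActivationEnergy:
        """Hand-off object usable by the kinetic forward model."""
        if self.mode == "linear":
            return ActivationEnergy.constant(self.E)
        return ActivationEnergy.from_kissinger_quadratic(
            self.b, self.c, self.validity_window[0], self.validity_window[1]
        )

    def E_at(self, T: float) -> float:
        return activation_energy_at(self, T)


def _kissinger_xy(q_plus, Tp_K):
    q = np.asarray(q_plus, dtype=float) / 60.0  # degC/min -> K/s
    Tp = np.asarray(Tp_K, dtype=float)
    if np.any(q <= 0) or np.any(Tp <= 0):
        raise ValueError("heating rates and peak temperatures must be positive")
    return 1.0 / Tp, np.log(q / Tp**2)


def kissinger_fit(q_plus, Tp_K, step_index: int = 1) -> KissingerResult:
    """Ordinary least squares of ln(q/Tp^2) on 1/Tp; E = -slope * R.

    The heating-rate unit only shifts the intercept, leaving E unchanged.
    """
    x, y = _kissinger_xy(q_plus, Tp_K)
    if len(x) < 3:
        raise ValueError("at least 3 (q, Tp) points are required")
    if len(np.unique(x)) < len(x):
        raise ValueError("duplicated Tp values make the fit singular")
    res = stats.linregress(x, y)
    return KissingerResult(
        step_index=step_index,
        mode="linear",
        E=-res.slope * GAS_CONSTANT,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        validity_window=(float(np.min(Tp_K)), float(np.max(Tp_K))),
    )


def kissinger_quadratic(q_plus, Tp_K, step_index: int = 1) -> KissingerResult:
    """Quadratic fit y = a + b*x + c*x**2 in the Kissinger coordinates.

    The temperature-dependent activation energy is the (negated, scaled)
    derivative dy/dx evaluated at x = 1/T: E(T) = -R*(b + 2c/T), valid for
    T between the smallest and largest fitted Tp.
    """
    x, y = _kissinger_xy(q_plus, Tp_K)
    if len(x) < 4:
        raise ValueError("at least 4 (q, Tp) points are required for the quadratic fit")
    c2, c1, c0 = np.polyfit(x, y, 2)
    yhat = np.polyval([c2, c1, c0], x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return KissingerResult(
        step_index=step_index,
        mode="quadratic",
        a=float(c0),
        b=float(c1),
        c=float(c2),
        r_squared=r2,
        validity_window=(float(np.min(Tp_K)), float(np.max(Tp_K))),
    )


def activation_energy_at(result: KissingerResult, T: float) -> float:
    """E(T) in J/mol; raises outside the validity window (clamping is the
    caller's explicit choice via ActivationEnergy.value_at(..., clamp=True))."""
    if result.mode == "linear":
        return float(result.E)
    lo, hi = result.validity_window
    if T < lo or T > hi:
        raise ValueError(f"T={T:.2f} K outside validity window [{lo:.2f}, {hi:.2f}] K")
    return -GAS_CONSTANT * (result.b + 2.0 * result.c / T)


def select_E_mode(q_plus, Tp_K, p_threshold: float = 0.05) -> str:
    """Choose between constant E and E(T) for one step's Kissinger points.

    Quadratic is adopted iff the extra-sum-of-squares F-test for the
    quadratic term is significant (p <= ``p_threshold``; ties go to
    quadratic) AND the resulting E(T) stays positive over the validity
    window.  Exactly collinear points select linear.
    """
    x, y = _kissinger_xy(q_plus, Tp_K)
    if len(x) < 4:
        return "linear"
    lin = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((y - np.polyval(lin, x)) ** 2))
    quad = np.polyfit(x, y, 2)
    rss_quad = float(np.sum((y - np.polyval(quad, x)) ** 2))
    scale = float(np.sum(y**2)) + 1.0
    if rss_lin <= 1e-20 * scale:  # numerically collinear
        return "linear"
    dof = len(x) - 3
    if dof <= 0 or rss_quad <= 0:
        return "quadratic" if rss_quad < rss_lin else "linear"
    F = (rss_lin - rss_quad) / (rss_quad / dof)
    p = float(stats.f.sf(F, 1, dof))
    if p > p_threshold:
        return "linear"
    # require a physically sensible (positive) E over the window
    res = kissinger_quadratic(q_plus, Tp_K)
    Ts = np.linspace(res.validity_window[0], res.validity_window[1], 64)
    E = -GAS_CONSTANT * (res.b + 2.0 * res.c / Ts)
    return "quadratic" if np.all(E > 0) else "linear"


class KissingerAnalysis:
    """Activation-energy analysis over a set of constant-rate TGA curves.

    Parameters
    ----------
    curves :
        One curve per heating rate (optionally spanning several atmospheres;
        each atmosphere is analyzed separately).
    n_steps :
        Number of consecutive mass-loss steps to track.
    delta_T, prominence_frac :
        Passed to the derivative estimator / peak finder.
    """

    def __init__(
        self,
        curves: list[TGACurve],
        n_steps: int = 3,
        delta_T: float = 2.0,
        prominence_frac: float = 0.05,
    ):
        self.curves = list(curves)
        self.n_steps = n_steps
        self.delta_T = delta_T
        self.prominence_frac = prominence_frac
        self._peaks: pd.DataFrame | None = None

    @property
    def peaks(self) -> pd.DataFrame:
        if self._peaks is None:
            self._peaks = peak_table(
                self.curves,
                n_steps=self.n_steps,
                delta_T=self.delta_T,
                prominence_frac=self.prominence_frac,
            )
        return self._peaks

    def fit(self, mode: str = "auto", p_threshold: float = 0.05) -> "KissingerResults":
        """Fit each (atmosphere, step) group; mode 'auto' applies the F-test
        rule per group, 'linear'/'quadratic' force one form."""
        results: dict[tuple[str, int], KissingerResult] = {}
        for (atmo, step), grp in self.peaks.groupby(["atmosphere", "step_index"]):
            q = grp["q_plus"].to_numpy()
            tp = grp["Tp_K"].to_numpy()
            use = mode if mode != "auto" else select_E_mode(q, tp, p_threshold)
            if use == "quadratic":
                res = kissinger_quadratic(q, tp, step_index=int(step))
            else:
                res = kissinger_fit(q, tp, step_index=int(step))
            results[(atmo, int(step))] = res
        return KissingerResults(self, results)


@dataclass
class KissingerResults:
    """Fitted Kissinger analysis with per-(atmosphere, step) results."""

    analysis: KissingerAnalysis
    results: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.results[key]

    def fixed_E_for_curve(self, curve: TGACurve) -> list[float]:
        """Per-curve constant activation energies for the sc-MKA hand-off.

        For linear-mode steps this is the fitted E; for temperature-dependent
        steps it is E evaluated at that specific curve's peak temperature
        E(Tp), which fixes a constant per-curve value.
        """
        peaks = self.analysis.peaks
        sel = peaks[
            (peaks["atmosphere"] == curve.atmosphere)
            & (np.isclose(peaks["q_plus"], curve.q_plus))
        ].sort_values("step_index")
        out = []
        for _, row in sel.iterrows():
            res = self.results[(curve.atmosphere, int(row["step_index"]))]
            if res.mode == "linear":
                out.append(float(res.E))
            else:
                lo, hi = res.validity_window
                Tp = float(np.clip(row["Tp_K"], lo, hi))
                out.append(activation_energy_at(res, Tp))
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for (atmo, step), r in sorted(self.results.items()):
            E_repr = r.E if r.mode == "linear" else None
            rows.append(
                {
                    "atmosphere": atmo,
                    "step_index": step,
                    "mode": r.mode,
                    "E_kJ_mol": None if E_repr is None else E_repr / 1000.0,
                    "r_squared": r.r_squared,
                    "b": r.b,
                    "c": r.c,
                    "T_window_C": None
                    if r.validity_window is None
                    else tuple(round(kelvin_to_celsius(v), 2) for v in r.validity_window),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {}
        for (atmo, step), r in self.results.items():
            out[f"{atmo}/step{step}"] = {
                "mode": r.mode,
                "E_J_mol": r.E,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "validity_window_K": r.validity_window,
            }
        return out
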