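"""Single-curve multivariate kinetic analysis (sc-MKA).

Each mass-loss curve is fit separately by bounded nonlinear least squares
(Levenberg-Marquardt) of the consecutive three-step autocatalytic model,
with the three activation energies held fixed at values determined
independently (Kissinger analysis).  Fixing E removes the strong E/ln A
degeneracy (kinetic compensation effect) and makes the remaining
parameters -- log10(A), M, N per step plus the step weights w1, w2 --
identifiable from a single measurement, which is what exposes their
heating-rate dependence across a measurement series.

The objective is the unweighted residual sum of squares between observed
and calculated mass curves, in percent-of-initial-mass units.

The optimizer is deterministic: a fixed multistart grid over the
autocatalytic exponents is evaluated, the most promising starts are
polished with Levenberg-Marquardt, and the best final RSS wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd

from .curves import TGACurve
from .kinetic import (
    GAS_CONSTANT,
    ActivationEnergy,
    ConsecutiveModel,
    StepKinetics,
    integrate,
)
from .kissinger import DerivativeSeries, find_step_peaks, mass_derivative
from .programs import celsius_to_kelvin, make_linear_ramp

__all__ = [
    "FitSpec",
    "SingleCurveKineticModel",
    "SingleCurveKineticResults",
    "rss",
    "fit_quality",
    "fit_curve",
    "build_trend_table",
]

DEFAULT_BOUNDS = {
    "log10_A": (2.0, 20.0),
    "M": (0.0, 3.0),
    "N": (0.05, 12.0),
}


def rss(observed, calculated) -> float:
    """Sum of squared residuals between two equal-length series."""
    obs = np.asarray(observed, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if obs.shape != cal.shape or obs.size < 1:
        raise ValueError("observed and calculated series must have equal nonzero length")
    return float(np.sum((obs - cal) ** 2))


def fit_quality(observed, calculated) -> float:
    """Squared Pearson correlation between observed and calculated series.

    A constant calculated series has zero covariance and scores 0 by
    convention; a constant *observed* series makes the quality undefined.
    """
    obs = np.asarray(observed, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if obs.size < 3 or obs.shape != cal.shape:
        raise ValueError("need >= 3 paired points")
    so = float(np.std(obs))
    if so == 0:
        raise ValueError("observed series has zero variance; quality undefined")
    sc = float(np.std(cal))
    if sc == 0:
        return 0.0
    r = float(np.corrcoef(obs, cal)[0, 1])
    return r * r


@dataclass(frozen=True)
class FitSpec:
    """Configuration of a single-curve fit.

    fixed_E
        Three per-step activation energies in J/mol (the Kissinger
        hand-off); never optimized.
    delta_m_mode
        "fixed_from_data": total mass change taken from the final plateau
        (mean of the last 2 % of points; requires the curve to actually
        reach a plateau).  "fixed_value": use ``delta_m_value``.
        "free": optimized together with the kinetic parameters.
    multistart_M / multistart_N
        Grid of autocatalytic-exponent start values applied to all three
        steps; pre-exponentials are initialized per start by matching each
        step's observed peak loss rate.
    n_polish
        Number of best-scoring starts polished with Levenberg-Marquardt
        (every start's initial RSS is still evaluated and reported).
    fit_points
        Curves are subsampled evenly to at most this many points for the
        objective.
    """

    fixed_E: tuple[float, float, float]
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    delta_m_mode: str = "fixed_from_data"
    delta_m_value: float | None = None
    m_t0: float = 1.0
    multistart_M: tuple = (0.1, 0.5, 1.0)
    multistart_N: tuple = (0.5, 1.5, 4.0)
    n_polish: int = 3
    max_nfev: int = 2000
    xtol: float = 1e-10
    ftol: float = 1e-10
    fit_points: int = 400
    rtol: float = 1e-7
    atol: float = 1e-10
    seed_eps: float = 1e-8
    peak_Tps_C: tuple | None = None  # per-step DTG peak temps; auto-detected if None

    def __post_init__(self):
        if len(self.fixed_E) != 3 or any(E <= 0 for E in self.fixed_E):
            raise ValueError("fixed_E must be three positive values (J/mol)")
        if self.delta_m_mode not in ("fixed_from_data", "fixed_value", "free"):
            raise ValueError(f"unknown delta_m_mode {self.delta_m_mode!r}")
        if self.delta_m_mode == "fixed_value" and self.delta_m_value is None:
            raise ValueError("delta_m_value required with delta_m_mode='fixed_value'")


class SingleCurveKineticModel:
    """sc-MKA model for one TGA curve: fixed-E consecutive autocatalytic fit.

    Parameters
    ----------
    curve :
        The measured (or synthetic) mass-loss curve; must cover the full
        decomposition when ``delta_m_mode="fixed_from_data"``.
    spec :
        Fit configuration, including the three fixed activation energies.
    """

    def __init__(self, curve: TGACurve, spec: FitSpec):
        self.curve = curve
        self.spec = spec
        self._prepare()

    # -- data preparation ---------------------------------------------------

    def _prepare(self):
        c, spec = self.curve, self.spec
        t = c.t - c.t[0]
        T_K = celsius_to_kelvin(c.T_C)
        n = len(c)
        if n < 10:
            raise ValueError("curve too short")

        # heating program reconstruction: nominal rate when recorded (exact
        # for constant-rate runs, jitter shifts only the offset), otherwise
        # the least-squares slope of T on t
        if c.q_plus is not None:
            rate = float(c.q_plus) / 60.0
        else:
            rate = float(np.polyfit(t, T_K, 1)[0])
        if rate <= 0:
            raise ValueError("curve is not a heating ramp")
        T_end = float(T_K[0]) + rate * float(t[-1])
        self.program = make_linear_ramp(float(T_K[0]), T_end + 1e-9 * max(T_end, 1.0), rate)

        self.m_t0 = spec.m_t0
        if spec.delta_m_mode == "fixed_value":
            self.delta_m = float(spec.delta_m_value)
            self.delta_m_free = False
        elif spec.delta_m_mode == "fixed_from_data":
            self._require_plateau()
            k = max(2, int(round(0.02 * n)))
            self.delta_m = float(np.mean(c.m[-k:])) - self.m_t0
            self.delta_m_free = False
        else:
            k = max(2, int(round(0.02 * n)))
            self.delta_m = float(np.mean(c.m[-k:])) - self.m_t0  # starting value
            self.delta_m_free = True

        # even subsampling for the objective
        if n > spec.fit_points:
            idx = np.unique(np.round(np.linspace(0, n - 1, spec.fit_points)).astype(int))
        else:
            idx = np.arange(n)
        self._idx = idx
        self.t_fit = t[idx]
        self.m_obs = np.asarray(c.m, dtype=float)[idx]

    def _require_plateau(self):
        c = self.curve
        deriv = mass_derivative(c)
        k = max(3, int(round(0.05 * len(deriv.T_C))))
        tail = np.abs(deriv.dm_dT[-k:])
        peak = float(np.max(np.abs(deriv.dm_dT)))
        # median over the tail: robust to per-point noise, still flags a
        # decomposition that is genuinely ongoing at the end of the scan
        if peak <= 0 or float(np.median(tail)) > 0.02 * peak:
            raise ValueError(
                "curve does not reach a final plateau; cannot fix delta_m from "
                "data (use delta_m_mode='fixed_value' or 'free')"
            )

    # -- forward model ------------------------------------------------------

    def _consecutive(self, theta: dict) -> ConsecutiveModel:
        steps = tuple(
            StepKinetics(
                E=ActivationEnergy.constant(self.spec.fixed_E[i]),
                A=10.0 ** theta[f"log10_A{i + 1}"],
                M=theta[f"M{i + 1}"],
                N=theta[f"N{i + 1}"],
            )
            for i in range(3)
        )
        w1 = theta["w1"]
        w2 = theta["w2f"] * (1.0 - w1)
        delta_m = theta.get("delta_m", self.delta_m)
        return ConsecutiveModel(
            steps=steps, w1=w1, w2=w2, delta_m=delta_m,
            m_t0=self.m_t0, seed_eps=self.spec.seed_eps,
        )

    def _forward(self, theta: dict) -> np.ndarray:
        model = self._consecutive(theta)
        traj = integrate(
            model, self.program, self.t_fit, rtol=self.spec.rtol, atol=self.spec.atol
        )
        return traj.m

    def _residual_pct(self, theta: dict) -> np.ndarray:
        return (self.m_obs - self._forward(theta)) * 100.0

    # -- initialization -----------------------------------------------------

    def _detected_peaks(self) -> list[float]:
        if self.spec.peak_Tps_C is not None:
            return sorted(self.spec.peak_Tps_C)
        deriv = mass_derivative(self.curve)
        return find_step_peaks(deriv, n_steps=3)

    def _start_points(self) -> list[dict]:
        """Deterministic multistart grid with peak-rate matched log10_A."""
        spec = self.spec
        tps = self._detected_peaks()
        deriv = mass_derivative(self.curve)
        rate_K_s = self.program.segments[0].rate
        adm = abs(self.delta_m) if self.delta_m != 0 else 1.0

        # rough per-step weights from mass levels at mid-valley temperatures
        Tmid = [(tps[0] + tps[1]) / 2.0, (tps[1] + tps[2]) / 2.0]
        m_interp = np.interp(Tmid, self.curve.T_C, self.curve.m)
        a1 = float(np.clip((self.m_t0 - m_interp[0]) / adm, 0.02, 0.9))
        a12 = float(np.clip((self.m_t0 - m_interp[1]) / adm, a1 + 0.02, 0.95))
        w1_0, w2_0 = a1, a12 - a1
        w_est = [w1_0, w2_0, max(1.0 - a12, 0.02)]

        # observed peak loss rates (dm/dT * heating rate -> dm/dt)
        peak_rates = []
        for tp in tps:
            i = int(np.argmin(np.abs(deriv.T_C - tp)))
            peak_rates.append(abs(deriv.dm_dT[i]) * rate_K_s)

        starts = []
        lo_A, hi_A = spec.bounds["log10_A"]
        for gm in spec.multistart_M:
            for gn in spec.multistart_N:
                theta = {"w1": w1_0, "w2f": w2_0 / max(1.0 - w1_0, 1e-9)}
                f_half = 0.5 ** (gm + gn)
                for i, tp in enumerate(tps):
                    Tp_K = celsius_to_kelvin(tp)
                    dalpha_dt = peak_rates[i] / (adm * w_est[i])
                    k_needed = max(dalpha_dt / f_half, 1e-30)
                    log10_A = math.log10(k_needed) + spec.fixed_E[i] / (
                        GAS_CONSTANT * Tp_K * math.log(10.0)
                    )
                    theta[f"log10_A{i + 1}"] = float(np.clip(log10_A, lo_A, hi_A))
                    theta[f"M{i + 1}"] = gm
                    theta[f"N{i + 1}"] = gn
                if self.delta_m_free:
                    theta["delta_m"] = self.delta_m
                starts.append(theta)
        return starts

    def _make_params(self, theta: dict) -> lmfit.Parameters:
        spec = self.spec
        p = lmfit.Parameters()
        lo_A, hi_A = spec.bounds["log10_A"]
        lo_M, hi_M = spec.bounds["M"]
        lo_N, hi_N = spec.bounds["N"]
        for i in range(1, 4):
            p.add(f"log10_A{i}", value=theta[f"log10_A{i}"], min=lo_A, max=hi_A)
            p.add(f"M{i}", value=min(max(theta[f"M{i}"], lo_M), hi_M), min=lo_M, max=hi_M)
            p.add(f"N{i}", value=min(max(theta[f"N{i}"], lo_N), hi_N), min=lo_N, max=hi_N)
        p.add("w1", value=theta["w1"], min=0.0, max=1.0)
        p.add("w2f", value=min(max(theta["w2f"], 0.0), 1.0), min=0.0, max=1.0)
        if self.delta_m_free:
            p.add("delta_m", value=theta["delta_m"], min=-1.0, max=0.0)
        return p

    # -- fitting ------------------------------------------------------------

    def fit(self, start: dict | None = None) -> "SingleCurveKineticResults":
        """Run the multistart Levenberg-Marquardt optimization.

        ``start`` overrides the multistart grid with a single explicit
        initialization (a mapping with keys log10_A1..3, M1..3, N1..3, w1,
        w2 -- w2 is converted internally).
        """
        if start is not None:
            theta = dict(start)
            if "w2" in theta and "w2f" not in theta:
                w1 = theta["w1"]
                theta["w2f"] = theta.pop("w2") / max(1.0 - w1, 1e-12)
            starts = [theta]
        else:
            starts = self._start_points()

        start_rss = []
        for th in starts:
            try:
                start_rss.append(rss(self.m_obs * 100.0, self._forward(th) * 100.0))
            except Exception:
                start_rss.append(float("inf"))
        order = np.argsort(start_rss, kind="stable")
        n_polish = min(self.spec.n_polish, len(starts)) if start is None else 1

        def objective(params):
            return self._residual_pct({k: params[k].value for k in params})

        best = None
        minim_results = []
        for j in order[:n_polish]:
            params = self._make_params(starts[j])
            out = lmfit.minimize(
                objective,
                params,
                method="leastsq",
                max_nfev=self.spec.max_nfev,
                xtol=self.spec.xtol,
                ftol=self.spec.ftol,
            )
            final = float(np.sum(np.asarray(out.residual) ** 2))
            minim_results.append((int(j), final, out))
            if best is None or final < best[1]:
                best = (int(j), final, out)

        j_best, rss_best, out = best
        theta = {k: out.params[k].value for k in out.params}
        m_cal = self._forward(theta)
        return SingleCurveKineticResults(
            model=self,
            theta=theta,
            consecutive_model=self._consecutive(theta),
            rss=rss(self.m_obs * 100.0, m_cal * 100.0),
            residuals=self.m_obs - m_cal,
            m_calculated=m_cal,
            fit_quality=fit_quality(self.m_obs, m_cal),
            start_rss=[float(v) for v in start_rss],
            winning_start=j_best,
            nfev=int(out.nfev),
            success=bool(out.success),
            lmfit_result=out,
        )


@dataclass
class SingleCurveKineticResults:
    """Fitted sc-MKA parameters and diagnostics for one curve."""

    model: SingleCurveKineticModel
    theta: dict
    consecutive_model: ConsecutiveModel
    rss: float
    residuals: np.ndarray
    m_calculated: np.ndarray
    fit_quality: float
    start_rss: list
    winning_start: int
    nfev: int
    success: bool
    lmfit_result: object = None

    @property
    def params(self) -> dict:
        """Flat parameter dictionary in reporting units."""
        cm = self.consecutive_model
        out = {}
        for i, s in enumerate(cm.steps, start=1):
            out[f"log10_A{i}"] = math.log10(s.A)
            out[f"M{i}"] = s.M
            out[f"N{i}"] = s.N
            out[f"E{i}_kJ_mol"] = self.model.spec.fixed_E[i - 1] / 1000.0
        out["w1"] = cm.w1
        out["w2"] = cm.w2
        out["delta_m"] = cm.delta_m
        return out

    def summary(self) -> pd.DataFrame:
        """Per-step parameter table plus global quantities."""
        cm = self.consecutive_model
        rows = []
        for i, s in enumerate(cm.steps, start=1):
            rows.append(
                {
                    "step": i,
                    "E_kJ_mol (fixed)": self.model.spec.fixed_E[i - 1] / 1000.0,
                    "log10_A_per_s": math.log10(s.A),
                    "M": s.M,
                    "N": s.N,
                    "I_pct": 100.0 * (cm.w1, cm.w2, cm.w3)[i - 1],
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["rss"] = self.rss
        df.attrs["fit_quality_r2"] = self.fit_quality
        df.attrs["delta_m_pct"] = 100.0 * cm.delta_m
        return df

    def to_dict(self) -> dict:
        meta = self.model.curve.meta
        return {
            "sample_id": meta.get("sample_id"),
            "atmosphere": meta.get("atmosphere"),
            "q_plus_C_per_min": meta.get("q_plus_C_per_min"),
            "params": self.params,
            "rss": self.rss,
            "fit_quality_r2": self.fit_quality,
            "winning_start": self.winning_start,
            "start_rss": self.start_rss,
            "nfev": self.nfev,
            "success": self.success,
        }


def fit_curve(curve: TGACurve, spec: FitSpec, start: dict | None = None) -> SingleCurveKineticResults:
    """Functional wrapper: fit one curve with the given spec."""
    return SingleCurveKineticModel(curve, spec).fit(start=start)


def build_trend_table(fits: list[SingleCurveKineticResults]) -> pd.DataFrame:
    """Cross-rate trend table, one row per fitted curve.

    I1/I2/I3 are the percentage contributions of the three mass-loss steps
    (100*w1, 100*w2, 100*(1-w1-w2)); rows sorted by (atmosphere, q_plus).
    """
    if not fits:
        raise ValueError("no fits given")
    rows = []
    for r in fits:
        cm = r.consecutive_model
        meta = r.model.curve.meta
        row = {
            "atmosphere": meta.get("atmosphere"),
            "q_plus": meta.get("q_plus_C_per_min"),
        }
        for i in range(1, 4):
            row[f"E{i}_kJ_mol"] = r.model.spec.fixed_E[i - 1] / 1000.0
            row[f"log10_A{i}"] = r.params[f"log10_A{i}"]
            row[f"M{i}"] = r.params[f"M{i}"]
            row[f"N{i}"] = r.params[f"N{i}"]
        row["I1"] = 100.0 * cm.w1
        row["I2"] = 100.0 * cm.w2
        row["I3"] = 100.0 * cm.w3
        row["delta_m_pct"] = 100.0 * cm.delta_m
        row["fit_quality_r2"] = r.fit_quality
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["atmosphere", "q_plus"])
    return df.reset_index(drop=True)
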