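"""Synthetic TGA study generator.

Emulates the experimental design of the underlying study: three consecutive
mass-loss steps, ten heating rates spanning 0.1-20 degC/min, scans from 30
to 550 degC, one fresh sample per scan, and two atmospheres (inert vs
oxidizing) represented by two distinct truth parameter sets.  The noise
model matches the stated instrument reproducibility: a systematic per-curve
temperature-axis offset within +-2 degC, +-3 % relative scatter on the step
magnitudes, +-2 % relative scatter on the overall mass loss, plus small
per-point mass noise.

The shipped "n2_like" and "air_like" truth models are synthetic stand-ins
constructed so that the three mass-loss-rate peaks at 10 degC/min fall near
275, 315 and 350 degC with realistic overlap; they are not fitted values
for any real compound.

All randomness flows from a single base seed.  Curve ``i`` of a study draws
from ``numpy.random.SeedSequence(entropy=base_seed, spawn_key=(i,))``; the
resulting per-curve seed is recorded in the manifest so any single curve can
be regenerated bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .curves import TGACurve
from .kinetic import (
    ActivationEnergy,
    ConsecutiveModel,
    StepKinetics,
    integrate,
    model_from_json,
    model_to_json,
)
from .programs import (
    HeatingProgram,
    celsius_to_kelvin,
    make_linear_ramp,
    rate_per_min_to_per_s,
)

__all__ = [
    "NoiseSpec",
    "StudyDesign",
    "default_study_design",
    "n2_like_model",
    "air_like_model",
    "generate_curve",
    "generate_study",
    "write_manifest",
    "read_manifest",
    "PAPER_Q_LIST",
]

#: The ten heating rates of the study design, degC/min.
PAPER_Q_LIST = (0.1, 0.2, 0.5, 1, 2, 3, 5, 7, 10, 20)

#: Hard cap on points per generated curve (low heating rates are long runs).
MAX_POINTS = 20_000


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic curves; all sigmas >= 0, seed mandatory
    whenever any noise term is nonzero."""

    mass_sigma: float = 0.0005  # per-point, as a fraction of m0
    temp_jitter_C: float = 2.0  # half-width of per-curve uniform T offset
    step_magnitude_rel_sigma: float = 0.03  # relative scatter of w1, w2
    total_loss_rel_sigma: float = 0.02  # relative scatter of delta_m
    seed: int | None = None

    def __post_init__(self):
        for name in ("mass_sigma", "temp_jitter_C", "step_magnitude_rel_sigma", "total_loss_rel_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.any_noise and self.seed is None:
            raise ValueError("a seed is mandatory when any noise term is nonzero")

    @property
    def any_noise(self) -> bool:
        return any(
            s > 0
            for s in (
                self.mass_sigma,
                self.temp_jitter_C,
                self.step_magnitude_rel_sigma,
                self.total_loss_rel_sigma,
            )
        )

    @staticmethod
    def noiseless() -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0, seed=None)


@dataclass(frozen=True)
class StudyDesign:
    """One curve per (atmosphere, heating rate), scanned over T_span."""

    q_list: tuple = PAPER_Q_LIST
    T_span_C: tuple = (30.0, 550.0)
    sampling_interval: float = 1.0  # s; effective interval enforces MAX_POINTS
    atmosphere_models: dict = field(default_factory=dict)

    def __post_init__(self):
        q = tuple(float(x) for x in self.q_list)
        if len(set(q)) != len(q) or any(x <= 0 for x in q):
            raise ValueError("q_list must be positive and unique")
        object.__setattr__(self, "q_list", q)
        if not self.T_span_C[1] > self.T_span_C[0]:
            raise ValueError("T_span must be increasing")


def _step(E_kJ: float, log10A: float, M: float, N: float) -> StepKinetics:
    return StepKinetics(E=ActivationEnergy.constant(E_kJ * 1000.0), A=10.0**log10A, M=M, N=N)


def n2_like_model() -> ConsecutiveModel:
    """Inert-atmosphere truth model (synthetic stand-in).

    Pre-exponentials are calibrated so the three mass-loss-rate peaks at
    10 degC/min sit near 268, 315 and 362 degC with the steps separated
    enough that each remains an individually detectable peak across the
    whole 0.1-20 degC/min design.
    """
    return ConsecutiveModel(
        steps=(
            _step(140.0, 11.864, 0.55, 1.20),
            _step(165.0, 13.049, 0.60, 1.30),
            _step(195.0, 14.434, 0.60, 1.60),
        ),
        w1=0.13,
        w2=0.47,
        delta_m=-0.90,
    )


def air_like_model() -> ConsecutiveModel:
    """Oxidizing-atmosphere truth model (synthetic stand-in)."""
    return ConsecutiveModel(
        steps=(
            _step(135.0, 11.319, 0.50, 1.10),
            _step(175.0, 13.991, 0.60, 1.40),
            _step(205.0, 15.118, 0.55, 1.40),
        ),
        w1=0.12,
        w2=0.33,
        delta_m=-0.82,
    )


def default_study_design() -> StudyDesign:
    return StudyDesign(
        atmosphere_models={"n2": n2_like_model(), "air": air_like_model()}
    )


def _curve_seed(base_seed: int, index: int) -> int:
    """Documented splitting scheme: per-curve seed from (base_seed, index)."""
    return int(np.random.SeedSequence(entropy=base_seed, spawn_key=(index,)).generate_state(1)[0])


def generate_curve(
    model: ConsecutiveModel,
    program: HeatingProgram,
    sampling_interval: float,
    noise: NoiseSpec,
    meta: dict | None = None,
) -> TGACurve:
    """Simulate one noisy TGA curve; deterministic given ``noise.seed``.

    Draw order (fixed contract): w1 factor, w2 factor, delta_m factor,
    temperature offset, then the per-point mass noise vector.  With all
    sigmas zero the output equals the forward model exactly on the same
    grid.  The temperature offset is drawn once per curve (a systematic
    run-to-run shift, matching how reproducibility is quoted along the T
    axis); mass noise is drawn per point.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")
    total = program.total_duration
    interval = sampling_interval
    if total / interval + 1 > MAX_POINTS:
        interval = total / (MAX_POINTS - 1)
    grid = program.time_grid(interval=interval)

    true_model = model
    T_offset = 0.0
    if noise.any_noise:
        rng = np.random.default_rng(noise.seed)
        f1 = 1.0 + noise.step_magnitude_rel_sigma * rng.standard_normal()
        f2 = 1.0 + noise.step_magnitude_rel_sigma * rng.standard_normal()
        fdm = 1.0 + noise.total_loss_rel_sigma * rng.standard_normal()
        T_offset = float(rng.uniform(-noise.temp_jitter_C, noise.temp_jitter_C))
        w1 = float(np.clip(model.w1 * f1, 0.0, 1.0))
        w2 = float(np.clip(model.w2 * f2, 0.0, 1.0 - w1))
        delta_m = float(np.clip(model.delta_m * fdm, -1.0, 1.0))
        true_model = replace(model, w1=w1, w2=w2, delta_m=delta_m)

    traj = integrate(true_model, program, output_grid=grid)
    m = traj.m.copy()
    T_C = np.asarray(traj.T_C, dtype=float) + T_offset
    if noise.any_noise and noise.mass_sigma > 0:
        m = m + noise.mass_sigma * true_model.m_t0 * rng.standard_normal(len(m))

    meta = dict(meta or {})
    meta.setdefault("seed", noise.seed)
    meta["T_offset_C"] = T_offset
    meta["truth"] = json.loads(model_to_json(true_model))
    return TGACurve(t=grid, T_C=T_C, m=m, meta=meta)


def generate_study(design: StudyDesign, noise: NoiseSpec) -> list[TGACurve]:
    """One curve per (atmosphere, heating rate), plus truth metadata.

    Curve order (and the seed-splitting index) is sorted atmosphere label
    first, then ascending heating rate.
    """
    if not design.atmosphere_models:
        raise ValueError("design has no atmosphere models")
    T0, T1 = (celsius_to_kelvin(T) for T in design.T_span_C)
    curves = []
    index = 0
    for atmo in sorted(design.atmosphere_models):
        model = design.atmosphere_models[atmo]
        for q in design.q_list:
            program = make_linear_ramp(T0, T1, rate_per_min_to_per_s(q))
            seed_i = _curve_seed(noise.seed, index) if noise.any_noise else None
            noise_i = replace(noise, seed=seed_i) if noise.any_noise else noise
            meta = {
                "sample_id": f"{atmo}_q{q:g}",
                "atmosphere": atmo,
                "q_plus_C_per_min": q,
                "initial_mass_mg": 5.0,
            }
            curves.append(
                generate_curve(model, program, design.sampling_interval, noise_i, meta)
            )
            index += 1
    return curves


def write_manifest(curves: list[TGACurve], path) -> None:
    """Persist per-curve truth parameters and seeds alongside curve files."""
    entries = []
    for c in curves:
        entries.append(
            {
                "sample_id": c.meta.get("sample_id"),
                "atmosphere": c.meta.get("atmosphere"),
                "q_plus_C_per_min": c.meta.get("q_plus_C_per_min"),
                "seed": c.meta.get("seed"),
                "T_offset_C": c.meta.get("T_offset_C"),
                "truth": c.meta.get("truth"),
            }
        )
    with open(path, "w") as fh:
        json.dump({"curves": entries}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    for entry in doc["curves"]:
        entry["truth_model"] = model_from_json(json.dumps(entry["truth"]))
    return doc
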