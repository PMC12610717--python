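"""The TGA curve container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TGACurve"]


@dataclass
class TGACurve:
    """A sampled mass-loss run: time (s), temperature (degC), relative mass.

    ``m`` is stored as a fraction of the initial mass (1.0 at the start for
    normalized data); the CSV boundary uses percent.  ``meta`` carries run
    metadata: sample_id, atmosphere, q_plus_C_per_min, initial_mass_mg and,
    for synthetic curves, the noise seed.
    """

    t: np.ndarray
    T_C: np.ndarray
    m: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.T_C = np.asarray(self.T_C, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        n = len(self.t)
        if not (len(self.T_C) == len(self.m) == n):
            raise ValueError("t, T_C and m must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def q_plus(self) -> float | None:
        """Nominal heating rate in degC/min, if recorded."""
        return self.meta.get("q_plus_C_per_min")

    @property
    def atmosphere(self) -> str | None:
        return self.meta.get("atmosphere")
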