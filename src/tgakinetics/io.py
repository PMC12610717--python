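"""File formats and run configuration.

Curves travel as plain CSV (``time_s,temperature_C,mass_pct``) with a JSON
sidecar (same stem, ``.meta.json``) holding run metadata.  Mass is a
percentage of initial mass on disk and a fraction in memory.  Formatting is
deterministic (fixed column order, 9 significant digits) so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .curves import TGACurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_curve_dir",
    "load_config",
    "config_hash",
    "CurveFormatError",
]

_HEADER = "time_s,temperature_C,mass_pct"


class CurveFormatError(ValueError):
    """Malformed curve file; message names the offending row where known."""


def write_curve(curve: TGACurve, path) -> Path:
    """Write a curve CSV (and its metadata sidecar) deterministically."""
    path = Path(path)
    if len(curve) == 0:
        raise CurveFormatError("refusing to write an empty curve")
    lines = [_HEADER]
    for t, T, m in zip(curve.t, curve.T_C, curve.m):
        lines.append(f"{t:.9g},{T:.9g},{m * 100.0:.9g}")
    path.write_text("\n".join(lines) + "\n")
    if curve.meta:
        meta_path = path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(curve.meta, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_curve(path) -> TGACurve:
    """Read a curve CSV plus sidecar metadata; validates format invariants."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text or text[0].strip() != _HEADER:
        raise CurveFormatError(
            f"{path.name}: expected header '{_HEADER}', got {text[0].strip() if text else 'empty file'!r}"
        )
    t, T_C, m_pct = [], [], []
    for i, line in enumerate(text[1:], start=2):
        parts = line.split(",")
        if len(parts) != 3:
            raise CurveFormatError(f"{path.name}: row {i}: expected 3 columns")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise CurveFormatError(f"{path.name}: row {i}: non-numeric value") from None
        if any(np.isnan(v) for v in vals):
            raise CurveFormatError(f"{path.name}: row {i}: NaN value")
        if not (0 < vals[2] <= 120):
            raise CurveFormatError(f"{path.name}: row {i}: mass_pct={vals[2]} outside (0, 120]")
        t.append(vals[0])
        T_C.append(vals[1])
        m_pct.append(vals[2])
    t = np.asarray(t)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise CurveFormatError(f"{path.name}: row {bad}: time not strictly increasing")
    meta = {}
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return TGACurve(t=t, T_C=np.asarray(T_C), m=np.asarray(m_pct) / 100.0, meta=meta)


def read_curve_dir(directory) -> list[TGACurve]:
    """All curve CSVs in a directory, sorted by file name."""
    directory = Path(directory)
    curves = [
        read_curve(p)
        for p in sorted(directory.glob("*.csv"))
        if not p.name.endswith(".meta.json")
    ]
    if not curves:
        raise CurveFormatError(f"no curve CSVs found in {directory}")
    return curves


# ---------------------------------------------------------------------------
# run configuration

_SCHEMA = {
    "seed": int,
    "log_level": str,
    "design": {
        "q_list": list,
        "T_span_C": list,
        "sampling_interval_s": (int, float),
        "atmospheres": list,
    },
    "noise": {
        "mass_sigma": (int, float),
        "temp_jitter_C": (int, float),
        "step_magnitude_rel_sigma": (int, float),
        "total_loss_rel_sigma": (int, float),
    },
    "kissinger": {
        "n_steps": int,
        "delta_T": (int, float),
        "prominence_frac": (int, float),
        "mode": str,
    },
    "fit": {
        "delta_m_mode": str,
        "fit_points": int,
        "n_polish": int,
        "max_nfev": int,
    },
    "predict": {
        "hold_temperatures_C": list,
        "hold_minutes": (int, float),
        "ramp_start_C": (int, float),
        "ramp_rate_C_per_min": (int, float),
        "resolution_s": (int, float),
        "thresholds": list,
    },
}


def _validate(doc: dict, schema: dict, prefix: str = "") -> None:
    for key, val in doc.items():
        if key not in schema:
            raise ValueError(f"unknown config key: {prefix}{key}")
        want = schema[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {prefix}{key} must be a mapping")
            _validate(val, want, prefix=f"{prefix}{key}.")
        elif not isinstance(val, want):
            raise ValueError(f"config key {prefix}{key} has wrong type {type(val).__name__}")


def load_config(path) -> dict:
    """Load and schema-validate a YAML run configuration (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    _validate(doc, _SCHEMA)
    return doc


def config_hash(doc: dict) -> str:
    """Stable short hash of a configuration for output provenance blocks."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
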