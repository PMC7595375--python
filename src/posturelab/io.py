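"""Trial file formats.

A trial is a CSV with columns ``t_s,x_hip_m,x_sho_m,torque_Nm,
platform_tilt_deg`` plus a JSON metadata sidecar (``<stem>.meta.json``)
carrying subject id, condition labels, sample rate and units.  Angles are
stored in degrees, translations in meters, torque in N*m.  Gzipped CSVs
(``.csv.gz``) are read and written transparently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SwayRecording", "TrialFormatError", "read_trial", "write_trial",
           "COLUMNS"]

COLUMNS = ["t_s", "x_hip_m", "x_sho_m", "torque_Nm", "platform_tilt_deg"]

_UNITS = {"t_s": "s", "x_hip_m": "m", "x_sho_m": "m",
          "torque_Nm": "N*m", "platform_tilt_deg": "deg"}


class TrialFormatError(ValueError):
    """Trial file violates the expected schema."""


@dataclass
class SwayRecording:
    """One trial's multichannel time series with condition labels."""

    t: np.ndarray  # s
    x_hip: np.ndarray  # m
    x_sho: np.ndarray  # m
    torque: np.ndarray  # N*m
    platform_tilt: np.ndarray  # deg
    sample_rate: float  # Hz
    visual: Optional[str] = None  # EO | LAB | ABS | EC
    platform: Optional[str] = None  # fixed | swayref | fixed_swayref | tilt | calibration
    subject_id: Optional[str] = None
    meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # ground truth etc.; not serialized

    def __post_init__(self):
        n = len(self.t)
        for name in ("x_hip", "x_sho", "torque", "platform_tilt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time base length {n}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".csv.gz", ".csv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".meta.json")
    return path.with_suffix(".meta.json")


def write_trial(rec: SwayRecording, path: str | Path) -> Path:
    """Write a recording as a trial CSV plus JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t_s": rec.t,
            "x_hip_m": rec.x_hip,
            "x_sho_m": rec.x_sho,
            "torque_Nm": rec.torque,
            "platform_tilt_deg": rec.platform_tilt,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "subject_id": rec.subject_id,
        "visual": rec.visual,
        "platform": rec.platform,
        "sample_rate_hz": rec.sample_rate,
        "units": _UNITS,
        **rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_trial(path: str | Path, rtol_dt: float = 1e-9) -> SwayRecording:
    """Read a trial CSV (+ sidecar if present) into a :class:`SwayRecording`.

    Validates the column schema and that the time base is strictly
    increasing with uniform spacing (to within ``rtol_dt`` seconds).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(
            f"{path}: missing required columns {missing} (line 1: header)"
        )
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrialFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise TrialFormatError(
            f"{path}: time column not strictly increasing at line {i + 3} "
            f"(t={t[i + 1]!r} after t={t[i]!r})"
        )
    dt0 = float(np.median(dt))
    bad = np.flatnonzero(np.abs(dt - dt0) > rtol_dt + 1e-12 * abs(dt0))
    if bad.size:
        i = int(bad[0])
        raise TrialFormatError(
            f"{path}: non-uniform time base at line {i + 3} "
            f"(dt={dt[i]:.12g} s vs median {dt0:.12g} s)"
        )

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    units = meta.get("units")
    if units is not None and units != _UNITS:
        raise TrialFormatError(
            f"{sidecar}: unit declaration {units} does not match the "
            f"required units {_UNITS}"
        )
    sample_rate = float(meta.get("sample_rate_hz", 1.0 / dt0))
    if abs(sample_rate - 1.0 / dt0) > 1e-6 * sample_rate:
        raise TrialFormatError(
            f"{path}: declared sample rate {sample_rate} Hz does not match "
            f"the time base ({1.0 / dt0:.6g} Hz)"
        )
    extra_meta = {
        k: v
        for k, v in meta.items()
        if k not in ("subject_id", "visual", "platform", "sample_rate_hz", "units")
    }
    return SwayRecording(
        t=t,
        x_hip=df["x_hip_m"].to_numpy(dtype=float),
        x_sho=df["x_sho_m"].to_numpy(dtype=float),
        torque=df["torque_Nm"].to_numpy(dtype=float),
        platform_tilt=df["platform_tilt_deg"].to_numpy(dtype=float),
        sample_rate=sample_rate,
        visual=meta.get("visual"),
        platform=meta.get("platform"),
        subject_id=meta.get("subject_id"),
        meta=extra_meta,
    )
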