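"""End-to-end analysis pipeline.

Per subject: fit the COM calibration on the quasi-static recording, turn
hip/shoulder translations into the angular COM trace for every trial,
compute spontaneous-sway velocities (fixed and sway-referenced segments)
and tilt-trial periodic/random powers, then run the combined two-way
repeated-measures ANOVA with simple contrasts plus per-platform post-hocs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import (
    AnovaResult,
    ContrastResult,
    normalize_outcomes,
    rm_anova_2way,
    simple_contrasts,
    single_level_posthoc,
)
from .com import (
    CalibrationCoefficients,
    com_angle,
    compute_com,
    cop_from_torque,
    fit_calibration,
)
from .io import SwayRecording, read_trial
from .metrics import cycle_decompose, lowpass, sway_velocity

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "PipelineResult",
    "PipelineError",
    "calibrate_subject",
    "recording_com_angle",
    "spontaneous_metrics",
    "tilt_metrics",
    "build_outcome_table",
    "analyze_outcomes",
    "analyze_study",
    "run_pipeline",
]

#: the four platform-condition outcome parameters entering the combined ANOVA
PLATFORM_PARAMS = (
    "sway_velocity_fixed",
    "sway_velocity_swayref",
    "periodic_power",
    "random_power",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and trial."""


@dataclass(frozen=True)
class AnalysisParams:
    """All analysis-stage settings (defaults follow the published protocol)."""

    filter_order: int = 2
    filter_cutoff_hz: float = 5.0
    discard_s: float = 15.0
    window_s: float = 30.0
    cycle_duration_s: float = 20.0
    n_cycles: int = 13
    discard_first_cycles: int = 1
    filter_tilt_trials: bool = False
    normalization: str = "zscore"  # zscore | log | raw
    reference: str = "EO"
    exclude: Sequence[str] = ()
    g: float = 9.81
    greenhouse_geisser: bool = False


@dataclass
class PipelineResult:
    """Bundle of pipeline outputs."""

    metrics: pd.DataFrame  # subject, visual, platform, value (raw units)
    anova: AnovaResult
    contrasts: ContrastResult
    posthoc: Dict[str, tuple]  # platform param -> (AnovaResult, ContrastResult)
    calibrations: Dict[str, CalibrationCoefficients]
    log: dict

    def group_means(self, platform_param: str) -> pd.Series:
        sub = self.metrics[self.metrics["platform"] == platform_param]
        return sub.groupby("visual", sort=False)["value"].mean()


def calibrate_subject(
    calibration: SwayRecording, body_mass: float, params: AnalysisParams
) -> CalibrationCoefficients:
    cop = cop_from_torque(calibration.torque, body_mass, g=params.g)
    return fit_calibration(calibration.x_hip, calibration.x_sho, cop)


def recording_com_angle(
    rec: SwayRecording,
    coeffs: CalibrationCoefficients,
    h_com: float,
) -> np.ndarray:
    """Angular COM trace (deg) of a trial via the calibration coefficients."""
    x_com = compute_com(rec.x_hip, rec.x_sho, coeffs)
    return com_angle(x_com, h_com)


def spontaneous_metrics(
    theta: np.ndarray,
    sample_rate: float,
    params: AnalysisParams,
    swayref_start_s: Optional[float] = None,
) -> Dict[str, float]:
    """Sway velocities of the fixed and sway-referenced segments of a
    combined trial (or of a single-segment trial when ``swayref_start_s`` is
    None, keyed ``sway_velocity_fixed`` only)."""
    spec = (params.filter_order, params.filter_cutoff_hz)
    filtered = lowpass(theta, params.filter_order, params.filter_cutoff_hz, sample_rate)
    out = {}
    if swayref_start_s is None:
        seg = {"sway_velocity_fixed": filtered}
    else:
        split = int(round(swayref_start_s * sample_rate))
        seg = {
            "sway_velocity_fixed": filtered[:split],
            "sway_velocity_swayref": filtered[split:],
        }
    for key, trace in seg.items():
        res = sway_velocity(
            trace,
            sample_rate,
            discard=params.discard_s,
            window=params.window_s,
            filter_spec=spec,
        )
        out[key] = res.sway_velocity_s
    return out


def tilt_metrics(
    theta: np.ndarray, sample_rate: float, params: AnalysisParams
) -> Dict[str, float]:
    """Periodic and random sway power of a tilt trial."""
    if params.filter_tilt_trials:
        theta = lowpass(theta, params.filter_order, params.filter_cutoff_hz, sample_rate)
    res = cycle_decompose(
        theta,
        cycle_duration=params.cycle_duration_s,
        n_cycles=params.n_cycles,
        sample_rate=sample_rate,
        discard_first=params.discard_first_cycles,
    )
    return {"periodic_power": res.periodic_power, "random_power": res.random_power}


def _group_recordings(recordings: Iterable[SwayRecording]) -> Dict[str, dict]:
    by_subject: Dict[str, dict] = {}
    for rec in recordings:
        entry = by_subject.setdefault(rec.subject_id, {"calibration": None, "trials": []})
        if rec.platform == "calibration":
            entry["calibration"] = rec
        else:
            entry["trials"].append(rec)
    return by_subject


def build_outcome_table(
    recordings: Iterable[SwayRecording],
    params: AnalysisParams = AnalysisParams(),
) -> tuple[pd.DataFrame, Dict[str, CalibrationCoefficients]]:
    """Per-trial scalar outcomes for a set of recordings.

    Returns a long table (subject, visual, platform, value) where
    ``platform`` is one of :data:`PLATFORM_PARAMS`, plus the per-subject
    calibration coefficients.
    """
    rows: List[dict] = []
    calibrations: Dict[str, CalibrationCoefficients] = {}
    for sid, entry in sorted(_group_recordings(recordings).items()):
        cal = entry["calibration"]
        if cal is None:
            raise PipelineError(f"calibration: no calibration recording for subject {sid!r}")
        mass = cal.meta.get("body_mass_kg")
        h_com = cal.meta.get("h_com_m")
        if mass is None or h_com is None:
            raise PipelineError(
                f"calibration: subject {sid!r} metadata lacks body_mass_kg/h_com_m"
            )
        try:
            coeffs = calibrate_subject(cal, mass, params)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"calibration: subject {sid!r}: {exc}") from exc
        calibrations[sid] = coeffs
        for rec in entry["trials"]:
            stage = f"{rec.platform}: subject {sid!r}, visual {rec.visual!r}"
            try:
                theta = recording_com_angle(rec, coeffs, h_com)
                if rec.platform == "tilt":
                    values = tilt_metrics(theta, rec.sample_rate, params)
                elif rec.platform == "fixed_swayref":
                    values = spontaneous_metrics(
                        theta,
                        rec.sample_rate,
                        params,
                        swayref_start_s=rec.meta.get(
                            "swayref_start_s", rec.duration / 2
                        ),
                    )
                elif rec.platform == "fixed":
                    values = spontaneous_metrics(theta, rec.sample_rate, params)
                elif rec.platform == "swayref":
                    values = {
                        "sway_velocity_swayref": spontaneous_metrics(
                            theta, rec.sample_rate, params
                        )["sway_velocity_fixed"]
                    }
                else:
                    raise PipelineError(f"metrics: unknown platform {rec.platform!r}")
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"metrics ({stage}): {exc}") from exc
            for key, value in values.items():
                rows.append(
                    {"subject": sid, "visual": rec.visual, "platform": key,
                     "value": float(value)}
                )
    return pd.DataFrame(rows), calibrations


def analyze_outcomes(
    metrics: pd.DataFrame,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[AnovaResult, ContrastResult, Dict[str, tuple]]:
    """Combined two-way RM-ANOVA (normalized outcomes), simple contrasts vs
    the reference visual condition, and per-platform-parameter post-hocs (on
    raw values)."""
    data = metrics[~metrics["subject"].isin(set(params.exclude))].copy()
    # stable factor ordering
    data = data.sort_values(
        ["subject", "platform", "visual"], kind="stable"
    ).reset_index(drop=True)
    normalized = normalize_outcomes(data, by="platform", method=params.normalization)
    anova = rm_anova_2way(
        normalized,
        within=("visual", "platform"),
        greenhouse_geisser=params.greenhouse_geisser,
    )
    contrasts = simple_contrasts(
        normalized, factor="visual", reference=params.reference, other="platform"
    )
    posthoc = {}
    for level in pd.unique(data["platform"]):
        posthoc[level] = single_level_posthoc(
            data, level, platform="platform", factor="visual",
            reference=params.reference,
        )
    return anova, contrasts, posthoc


def analyze_study(
    recordings: Iterable[SwayRecording],
    params: AnalysisParams = AnalysisParams(),
) -> PipelineResult:
    """Full in-memory pipeline: outcomes then statistics, with a run log."""
    metrics, calibrations = build_outcome_table(recordings, params)
    anova, contrasts, posthoc = analyze_outcomes(metrics, params)
    log = {
        "package_version": __version__,
        "params": asdict(params),
        "n_subjects": int(metrics["subject"].nunique()),
        "excluded": list(params.exclude),
        "calibrations": {
            sid: {"a": c.a, "b": c.b, "c": c.c, "residual_rms_m": c.residual_rms}
            for sid, c in calibrations.items()
        },
    }
    return PipelineResult(
        metrics=metrics,
        anova=anova,
        contrasts=contrasts,
        posthoc=posthoc,
        calibrations=calibrations,
        log=log,
    )


# ----------------------------------------------------------------------------
# file-based entry point


_RUNCONFIG_KEYS = {
    "data_dir", "out_dir", "filter_order", "filter_cutoff_hz", "discard_s",
    "window_s", "cycle_duration_s", "n_cycles", "discard_first_cycles",
    "filter_tilt_trials", "normalization", "reference", "exclude", "seed",
    "greenhouse_geisser",
}


@dataclass
class RunConfig:
    """Validated configuration for a file-based pipeline run."""

    data_dir: Path
    out_dir: Path
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("data_dir", "out_dir"):
            if key not in raw:
                raise ValueError(f"{path}: missing required key {key!r}")
        param_kwargs = {
            k: raw[k]
            for k in raw
            if k not in ("data_dir", "out_dir", "seed")
        }
        if "exclude" in param_kwargs:
            param_kwargs["exclude"] = tuple(param_kwargs["exclude"])
        params = AnalysisParams(**param_kwargs)
        return cls(
            data_dir=Path(raw["data_dir"]),
            out_dir=Path(raw["out_dir"]),
            params=params,
            seed=int(raw.get("seed", 0)),
        )


def _config_hash(params: AnalysisParams) -> str:
    blob = json.dumps(asdict(params), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_trials(data_dir: str | Path) -> List[SwayRecording]:
    data_dir = Path(data_dir)
    paths = sorted(data_dir.glob("*.csv")) + sorted(data_dir.glob("*.csv.gz"))
    if not paths:
        raise PipelineError(f"io: no trial CSVs found in {data_dir}")
    return [read_trial(p) for p in paths]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read trials from ``config.data_dir``, analyze, and write the result
    bundle (metrics/anova/contrasts/posthoc CSVs plus a JSON log) to
    ``config.out_dir``.  Input files are never modified."""
    recordings = load_trials(config.data_dir)
    result = analyze_study(recordings, config.params)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.anova.table.to_csv(out / "anova.csv", index=False)
    result.contrasts.table.to_csv(out / "contrasts.csv", index=False)
    posthoc_rows = []
    for level, (an, con) in result.posthoc.items():
        t = an.table.copy()
        t.insert(0, "platform", level)
        t.insert(1, "kind", "anova")
        posthoc_rows.append(t)
        t2 = con.table.copy()
        t2.insert(0, "platform", level)
        t2.insert(1, "kind", "contrast")
        posthoc_rows.append(t2)
    pd.concat(posthoc_rows, ignore_index=True).to_csv(
        out / "posthoc.csv", index=False
    )
    result.log["config_hash"] = _config_hash(config.params)
    result.log["seed"] = config.seed
    result.log["data_dir"] = str(config.data_dir)
    (out / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))
    return result
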