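"""Readers and writers for the package's plain-text interchange formats.

Force-plate and crank-torque time series travel as CSV (`time_s,force_n`;
`time_s,torque_left_nm[,torque_right_nm]`), per-stroke records as CSV
(`stroke_index,mean_torque_nm,cadence_rpm,power_w`), and session manifests
as JSON or YAML. Left and right crank columns are summed into total crank
torque on read. Headers are matched case-insensitively; timestamps must be
uniform to a small tolerance (jittered loggers are rejected rather than
silently resampled). Floats round-trip bit-exactly.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .types import (
    ForceTimeTrial,
    SprintSession,
    SprintTrial,
    StrokeSummary,
    TorqueTrace,
    ValidationError,
)

_FLOAT_FMT = "%.17g"


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _infer_fs(time_s: np.ndarray, path, tol_rel: float = 1e-6) -> float:
    dt = np.diff(time_s)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValidationError(f"{path}: time must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > tol_rel * med + 1e-12:
        raise ValidationError(
            f"{path}: non-uniform sampling (timestamp jitter exceeds tolerance)"
        )
    return 1.0 / med


def write_force_trial(trial: ForceTimeTrial, path) -> None:
    pd.DataFrame({"time_s": trial.time_s, "force_n": trial.force_n}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_force_trial(
    path,
    trial_type: str,
    baseline_window_s: Optional[Tuple[float, float]] = None,
) -> ForceTimeTrial:
    """Read a force-time CSV (`time_s,force_n`, case-insensitive header).

    When no baseline window is given, the first 30% of the record (capped
    at 1 s) is assumed to be quiet standing.
    """

    df = _read_csv(path)
    _require(df, ["time_s", "force_n"], path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(t, path)
    if baseline_window_s is None:
        baseline_window_s = (float(t[0]), float(t[0]) + min(1.0, 0.3 * (t[-1] - t[0])))
    return ForceTimeTrial(
        time_s=t,
        force_n=df["force_n"].to_numpy(dtype=float),
        fs_hz=fs,
        trial_type=trial_type,
        baseline_window_s=tuple(baseline_window_s),
    )


def write_torque_trace(trace: TorqueTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "torque_left_nm": trace.torque_nm}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_torque_trace(path) -> TorqueTrace:
    """Read a crank-torque CSV; left and right columns are summed when both exist."""
    df = _read_csv(path)
    _require(df, ["time_s", "torque_left_nm"], path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(t, path)
    torque = df["torque_left_nm"].to_numpy(dtype=float)
    if "torque_right_nm" in df.columns:
        torque = torque + df["torque_right_nm"].to_numpy(dtype=float)
    return TorqueTrace(time_s=t, torque_nm=torque, fs_hz=fs)


def write_strokes(strokes: Sequence[StrokeSummary], path) -> None:
    pd.DataFrame(
        [
            {
                "stroke_index": s.stroke_index,
                "mean_torque_nm": s.mean_torque_nm,
                "cadence_rpm": s.cadence_rpm,
                "power_w": s.power_w,
            }
            for s in strokes
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_strokes(path) -> list:
    df = _read_csv(path)
    _require(df, ["stroke_index", "mean_torque_nm", "cadence_rpm", "power_w"], path)
    return [
        StrokeSummary(
            stroke_index=int(r.stroke_index),
            mean_torque_nm=float(r.mean_torque_nm),
            cadence_rpm=float(r.cadence_rpm),
            power_w=float(r.power_w),
        )
        for r in df.itertuples(index=False)
    ]


def read_sprint_trial(
    strokes_path, start_type: str, resistance_nm_per_kg: float, trace_path=None
) -> SprintTrial:
    return SprintTrial(
        start_type=start_type,
        resistance_nm_per_kg=resistance_nm_per_kg,
        strokes=read_strokes(strokes_path),
        trace=read_torque_trace(trace_path) if trace_path else None,
    )


# ---------------------------------------------------------------- manifests

_TIMEPOINTS = ("pre", "post")


def write_manifest(manifest: dict, path) -> None:
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(manifest, fh, sort_keys=True)
        else:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    """Read and validate a session manifest (JSON or YAML by extension)."""
    path = str(path)
    with open(path) as fh:
        manifest = (
            yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        )
    for key in ("participant", "timepoint", "body_mass_kg"):
        if key not in manifest:
            raise ValidationError(f"{path}: manifest missing {key!r}")
    if manifest["timepoint"] not in _TIMEPOINTS:
        raise ValidationError(f"{path}: timepoint must be one of {_TIMEPOINTS}")
    return manifest


def load_session(manifest: dict, base_dir="."):
    """Materialise a manifest: (IMTP trials, SprintSession).

    Referenced file paths are resolved relative to ``base_dir``; missing
    files surface as a descriptive error.
    """

    def _resolve(p):
        full = os.path.join(base_dir, p)
        if not os.path.exists(full):
            raise ValidationError(f"manifest references a missing file: {full}")
        return full

    imtp_trials = [
        read_force_trial(
            _resolve(entry["path"]),
            trial_type=entry["trial_type"],
            baseline_window_s=tuple(entry["baseline_window_s"])
            if "baseline_window_s" in entry
            else None,
        )
        for entry in manifest.get("imtp_trials", [])
    ]
    sprints = [
        read_sprint_trial(
            _resolve(entry["strokes_path"]),
            start_type=entry["start_type"],
            resistance_nm_per_kg=float(entry["resistance_nm_per_kg"]),
            trace_path=_resolve(entry["trace_path"]) if entry.get("trace_path") else None,
        )
        for entry in manifest.get("sprints", [])
    ]
    session = SprintSession(
        trials=sprints,
        body_mass_kg=float(manifest["body_mass_kg"]),
        participant=manifest["participant"],
        timepoint=manifest["timepoint"],
    )
    return imtp_trials, session
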