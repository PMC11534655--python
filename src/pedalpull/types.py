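"""Domain containers for neuromuscular profiling.

Two families of raw signal are handled: vertical ground-reaction force from
an isometric mid-thigh pull (IMTP) performed on a force plate, and total
crank torque from maximal sprint-cycling efforts on an isokinetic-style
ergometer. Derived-metric containers hold the scalar summaries practitioners
report (peak force, rate of force/torque development, torque-cadence and
power-cadence profile parameters) together with effect-size and correlation
results for pre/post training comparisons.

All containers are plain dataclasses over numpy arrays; validation raises
:class:`ValidationError` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EXPLOSIVE_1S = "explosive_1s"
MAX_5S = "max_5s"
TRIAL_TYPES = (EXPLOSIVE_1S, MAX_5S)

STATIONARY = "stationary"
ROLLING = "rolling"
START_TYPES = (STATIONARY, ROLLING)

#: External resistances (Nm per kg body mass) accepted for sprint trials.
ALLOWED_RESISTANCES = (0.0, 0.2, 0.4, 0.6)

#: rad/s per rpm; crank power P = T * cadence * RPM_TO_RAD_S.
RPM_TO_RAD_S = 2.0 * math.pi / 60.0


class ValidationError(ValueError):
    """Raised when a container's invariants are violated; names the field."""


class AnalysisError(RuntimeError):
    """Raised when an analysis step cannot produce a result."""


class OnsetNotFoundError(AnalysisError):
    """Raised when no signal onset can be detected."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name}: expected a 1-D array")
    return arr


def _check_uniform(time_s: np.ndarray, name: str, tol: float = 1e-9) -> float:
    dt = np.diff(time_s)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValidationError(f"{name}: time must be strictly increasing")
    if np.max(dt) - np.min(dt) > tol:
        raise ValidationError(
            f"{name}: non-uniform sampling (spread {np.max(dt) - np.min(dt):.3g} s "
            f"exceeds tolerance {tol:g} s)"
        )
    return float(np.median(dt))


@dataclass
class ForceTimeTrial:
    """One raw IMTP force-time record.

    Parameters
    ----------
    time_s, force_n
        Uniformly sampled time (s) and vertical force (N). The force is the
        raw plate signal, i.e. it includes the quiet-standing body-weight
        offset; net metrics subtract the baseline mean.
    fs_hz
        Sampling rate. Must agree with the time vector.
    trial_type
        ``"explosive_1s"`` (short, rate-focused pull) or ``"max_5s"``
        (sustained maximal pull).
    baseline_window_s
        ``(start, end)`` in seconds of quiet standing preceding the pull,
        used for the baseline mean/SD.
    min_duration_s
        Shortest admissible record. IMTP records keep the 0.3-s default;
        crank-torque downstroke segments reusing this container relax it.
    """

    time_s: np.ndarray
    force_n: np.ndarray
    fs_hz: float
    trial_type: str
    baseline_window_s: tuple
    min_duration_s: float = 0.3

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.force_n = _as_float_array(self.force_n, "force_n")
        if len(self.time_s) != len(self.force_n):
            raise ValidationError("force_n: length differs from time_s")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz: must be positive")
        if len(self.time_s) < self.min_duration_s * self.fs_hz:
            raise ValidationError(
                f"time_s: record shorter than {self.min_duration_s:g} s"
            )
        dt = _check_uniform(self.time_s, "time_s")
        if abs(dt - 1.0 / self.fs_hz) > 1e-6:
            raise ValidationError("fs_hz: inconsistent with time spacing")
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"trial_type: must be one of {TRIAL_TYPES}")
        b0, b1 = self.baseline_window_s
        if not (self.time_s[0] - 1e-12 <= b0 < b1 <= self.time_s[-1] + 1e-12):
            raise ValidationError("baseline_window_s: outside the record")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def baseline_slice(self) -> slice:
        b0, b1 = self.baseline_window_s
        i0 = int(np.searchsorted(self.time_s, b0 - 1e-12, side="left"))
        i1 = int(np.searchsorted(self.time_s, b1 + 1e-12, side="right"))
        return slice(i0, i1)


@dataclass
class IMTPMetrics:
    """Scalar summaries of one IMTP trial (or a best-trial aggregate).

    ``peak_force_n`` is net of the baseline (quiet-standing) force. RFD
    metrics are in N/s. ``canonical_pf`` / ``canonical_rfd`` flag whether the
    value came from the trial type the testing convention prescribes (peak
    force from 5-s trials, RFD from 1-s explosive trials).
    """

    onset_time_s: float
    onset_force_n: float
    peak_force_n: float
    time_to_pf_s: float
    rfd_0_100: float
    rfd_0_200: float
    rfd_avg: float
    rfd_peak: float
    trial_type: Optional[str] = None
    canonical_pf: bool = True
    canonical_rfd: bool = True

    METRIC_FIELDS = (
        "onset_time_s",
        "onset_force_n",
        "peak_force_n",
        "time_to_pf_s",
        "rfd_0_100",
        "rfd_0_200",
        "rfd_avg",
        "rfd_peak",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.METRIC_FIELDS}


@dataclass
class TorqueTrace:
    """Continuous total crank torque sampled at the logger rate (256 Hz)."""

    time_s: np.ndarray
    torque_nm: np.ndarray
    fs_hz: float = 256.0

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.torque_nm = _as_float_array(self.torque_nm, "torque_nm")
        if len(self.time_s) != len(self.torque_nm):
            raise ValidationError("torque_nm: length differs from time_s")
        if not np.all(np.isfinite(self.torque_nm)):
            raise ValidationError("torque_nm: non-finite values")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz: must be positive")
        _check_uniform(self.time_s, "time_s", tol=1e-6)


@dataclass
class StrokeSummary:
    """Per-downstroke record from the once-per-revolution logger."""

    stroke_index: int
    mean_torque_nm: float
    cadence_rpm: float
    power_w: float

    def __post_init__(self):
        if self.stroke_index < 1:
            raise ValidationError("stroke_index: 1-based, must be >= 1")
        if self.cadence_rpm < 0:
            raise ValidationError("cadence_rpm: must be non-negative")
        expected = self.mean_torque_nm * self.cadence_rpm * RPM_TO_RAD_S
        if np.isfinite(expected) and abs(self.power_w - expected) > max(
            1.0, 0.02 * abs(expected)
        ):
            raise ValidationError(
                "power_w: inconsistent with mean_torque_nm * cadence (P = T*c*2pi/60)"
            )


@dataclass
class SprintTrial:
    """One 5-s sprint: start condition, resistance, trace and stroke records."""

    start_type: str
    resistance_nm_per_kg: float
    strokes: list
    trace: Optional[TorqueTrace] = None

    def __post_init__(self):
        if self.start_type not in START_TYPES:
            raise ValidationError(f"start_type: must be one of {START_TYPES}")
        if not any(
            abs(self.resistance_nm_per_kg - r) < 1e-9 for r in ALLOWED_RESISTANCES
        ):
            raise ValidationError(
                f"resistance_nm_per_kg: must be one of {ALLOWED_RESISTANCES}"
            )


@dataclass
class SprintSession:
    """All sprints for one participant-timepoint, with body mass for scaling."""

    trials: list
    body_mass_kg: float
    participant: Optional[str] = None
    timepoint: Optional[str] = None

    def __post_init__(self):
        if self.body_mass_kg <= 0:
            raise ValidationError("body_mass_kg: must be positive")

    def find_trial(self, start_type: str, resistance: float) -> Optional[SprintTrial]:
        for tr in self.trials:
            if tr.start_type == start_type and abs(
                tr.resistance_nm_per_kg - resistance
            ) < 1e-9:
                return tr
        return None


@dataclass
class ProfileFit:
    """Fitted torque-cadence line and zero-intercept power-cadence cubic.

    The torque-cadence relation is ``T(c) = tc_intercept + tc_slope * c``
    (intercept = theoretical maximal torque T0, x-intercept = theoretical
    maximal cadence RPMmax). The power-cadence relation is
    ``P(c) = a1*c + a2*c^2 + a3*c^3`` with the y-intercept pinned at zero.
    """

    tc_slope: float
    tc_intercept: float
    tc_r2: float
    pc_coeffs: tuple
    pc_r2: float
    n_points: int
    tc_residual_sd: float = float("nan")
    pc_residual_sd: float = float("nan")

    def power_at(self, cadence_rpm):
        c = np.asarray(cadence_rpm, dtype=float)
        a1, a2, a3 = self.pc_coeffs
        return a1 * c + a2 * c**2 + a3 * c**3

    def torque_at(self, cadence_rpm):
        c = np.asarray(cadence_rpm, dtype=float)
        return self.tc_intercept + self.tc_slope * c


@dataclass
class CyclingMetrics:
    """Session-level sprint-cycling summary.

    Observed values (``ppo_w``, ``rpm_peak``, ``t_peak_nm``) are maxima over
    all sprints; profile-derived values (``t0_nm``, ``pmax_w``,
    ``rpmmax_rpm``, ``rpmopt_rpm``) come from the fitted torque-cadence and
    power-cadence relationships; RTD metrics come from downstrokes 2-3 of
    the 0.6 Nm/kg stationary sprint.
    """

    ppo_w: float
    ppo_per_bm: float
    rpm_peak: float
    t_peak_nm: float
    rtd_0_100: float
    rtd_0_200: float
    rtd_avg: float
    rtd_peak: float
    t0_nm: float
    pmax_w: float
    rpmmax_rpm: float
    rpmopt_rpm: float
    tc_r2: float
    pc_r2: float
    n_points: int = 0
    fit: Optional[ProfileFit] = None

    METRIC_FIELDS = (
        "ppo_w",
        "ppo_per_bm",
        "rpm_peak",
        "t_peak_nm",
        "rtd_0_100",
        "rtd_0_200",
        "rtd_avg",
        "rtd_peak",
        "t0_nm",
        "pmax_w",
        "rpmmax_rpm",
        "rpmopt_rpm",
        "tc_r2",
        "pc_r2",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.METRIC_FIELDS}


@dataclass
class EffectSizeResult:
    """Bias-corrected Hedge's g with its 95% CI and magnitude label."""

    g: float
    ci_low: float
    ci_high: float
    label: str

    def __post_init__(self):
        if not (self.ci_low <= self.g <= self.ci_high):
            raise ValidationError("ci_low/ci_high: must bracket g")


@dataclass
class CorrelationResult:
    """Pearson r with two-tailed p and a magnitude label."""

    r: float
    p: float
    n: int
    label: str

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError("r: outside [-1, 1]")
        if not (0 < self.p <= 1):
            raise ValidationError("p: outside (0, 1]")
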