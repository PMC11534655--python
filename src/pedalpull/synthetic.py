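"""Synthetic signal and cohort generators with known ground truth.

Every downstream stage of the package is testable without instrument data:
this module emulates (a) IMTP force-time trials as a baseline-noise-plus-
rapid-rise curve, (b) five-sprint cycling sessions whose per-stroke torques
sit on a known linear torque-cadence relationship, and (c) paired pre/post
cohorts with prescribed means, SDs and training effects.

Generative choices (none of which are dictated by instrument physics):

* IMTP force rises as a truncated logistic, normalised so the deterministic
  curve attains exactly ``pf_true`` above baseline at ``peak_time_s``, then
  decays mildly — isometric pulls crest and fade rather than holding a
  perfect plateau, and a unique crest keeps the noisy-peak statistics
  honest. Noise is Gaussian and white; the analysis chain applies no
  filtering, so white noise is exactly what it must tolerate.
* A linear torque-cadence truth makes the induced power-cadence curve an
  exact parabola ``P(c) = (2*pi/60) * t0 * c * (1 - c/rpmmax)``, whose apex
  ``Pmax = pi*t0*rpmmax/120`` at ``c = rpmmax/2`` is a free closed-form
  oracle for the zero-intercept cubic fit.
* The 256-Hz crank trace is one half-sine torque lobe per downstroke with a
  short zero-torque trough (top/bottom dead centre) occupying a fixed
  fraction of the stroke period; each lobe is scaled so its mean equals the
  stroke's recorded mean torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    ALLOWED_RESISTANCES,
    EXPLOSIVE_1S,
    MAX_5S,
    ROLLING,
    RPM_TO_RAD_S,
    STATIONARY,
    START_TYPES,
    TRIAL_TYPES,
    ForceTimeTrial,
    SprintSession,
    SprintTrial,
    StrokeSummary,
    TorqueTrace,
    ValidationError,
)


class GenerationError(RuntimeError):
    """Raised when a ground-truth specification cannot be realised."""


#: the five sprint conditions of the testing protocol:
#: stationary starts at 0.2/0.4/0.6 Nm per kg body mass, rolling starts
#: (~80 rpm lead-in) at 0.0/0.2 Nm per kg.
DEFAULT_CONDITIONS: Tuple[Tuple[str, float], ...] = (
    (STATIONARY, 0.2),
    (STATIONARY, 0.4),
    (STATIONARY, 0.6),
    (ROLLING, 0.0),
    (ROLLING, 0.2),
)


@dataclass
class IMTPGroundTruth:
    """Generative parameters for one synthetic IMTP trial.

    ``pf_true`` is the net peak force above the quiet-standing baseline;
    ``onset_true_s`` is where the deterministic rise departs from baseline
    (the curve is truncated to exactly baseline before it). The logistic
    midpoint and steepness shape the rise; after ``peak_time_s`` the curve
    decays at ``post_peak_decay`` per second.
    """

    baseline_force: float = 800.0
    pf_true: float = 2000.0
    rise_midpoint_s: float = 1.05
    rise_rate: float = 60.0
    onset_true_s: float = 1.0
    peak_time_s: float = 1.15
    post_peak_decay: float = 0.3
    noise_sd: float = 20.0
    fs_hz: float = 1000.0
    duration_s: float = 2.0
    trial_type: str = EXPLOSIVE_1S

    def __post_init__(self):
        if self.pf_true <= 0:
            raise ValidationError("pf_true: must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be non-negative")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz: must be positive")
        if not (self.onset_true_s < self.rise_midpoint_s < self.duration_s):
            raise ValidationError(
                "rise_midpoint_s: need onset_true_s < rise_midpoint_s < duration_s"
            )
        if not (self.rise_midpoint_s < self.peak_time_s <= self.duration_s):
            raise ValidationError(
                "peak_time_s: need rise_midpoint_s < peak_time_s <= duration_s"
            )
        if self.post_peak_decay < 0:
            raise ValidationError("post_peak_decay: must be non-negative")
        if self.rise_rate <= 0:
            raise ValidationError("rise_rate: must be positive")
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"trial_type: must be one of {TRIAL_TYPES}")
        if (self.onset_true_s - 0.05) * self.fs_hz < 100:
            raise ValidationError(
                "onset_true_s: too early to leave a 100-sample baseline window"
            )

    @classmethod
    def max_5s(cls, **overrides) -> "IMTPGroundTruth":
        """Defaults for a sustained 5-s maximal trial (slower rise, slow fade)."""
        params = dict(
            rise_midpoint_s=1.1,
            rise_rate=30.0,
            peak_time_s=1.5,
            post_peak_decay=0.05,
            duration_s=6.0,
            trial_type=MAX_5S,
        )
        params.update(overrides)
        return cls(**params)

    def deterministic_force(self, t: np.ndarray) -> np.ndarray:
        """Noise-free force curve at times ``t`` (includes the baseline offset)."""
        t = np.asarray(t, dtype=float)
        logistic = 1.0 / (1.0 + np.exp(-self.rise_rate * (t - self.rise_midpoint_s)))
        l_peak = 1.0 / (
            1.0 + math.exp(-self.rise_rate * (self.peak_time_s - self.rise_midpoint_s))
        )
        shape = np.where(
            t <= self.peak_time_s,
            logistic / l_peak,
            np.exp(-self.post_peak_decay * np.maximum(t - self.peak_time_s, 0.0)),
        )
        shape = np.where(t < self.onset_true_s, 0.0, shape)
        return self.baseline_force + self.pf_true * shape


def generate_imtp_trial(gt: IMTPGroundTruth, seed: int) -> ForceTimeTrial:
    """Generate one synthetic IMTP force-time trial.

    Deterministic given ``(gt, seed)``; the quiet-standing baseline window
    is set to end 50 ms before the true onset.
    """

    n = int(round(gt.duration_s * gt.fs_hz))
    t = np.arange(n) / gt.fs_hz
    rng = np.random.default_rng(seed)
    force = gt.deterministic_force(t) + rng.normal(0.0, gt.noise_sd, size=n)
    return ForceTimeTrial(
        time_s=t,
        force_n=force,
        fs_hz=gt.fs_hz,
        trial_type=gt.trial_type,
        baseline_window_s=(0.0, gt.onset_true_s - 0.05),
    )


@dataclass
class CyclingGroundTruth:
    """Generative parameters for one synthetic five-sprint session.

    The torque-cadence truth is the line ``T(c) = t0_true * (1 - c /
    rpmmax_true)``. Each sprint's per-stroke cadences approach a
    condition-dependent target geometrically: heavier external resistance
    gives a lower steady-state cadence, so sprints against 0.6 Nm/kg
    saturate at much lower cadence than unloaded rolling sprints. Defaults
    mirror the pre-training group means of the study population this
    package models (t0 165.2 Nm, rpmmax 232.2 rpm, body mass 76.8 kg).
    """

    t0_true: float = 165.2
    rpmmax_true: float = 232.2
    torque_noise_sd: float = 5.0
    body_mass_kg: float = 76.8
    conditions: Tuple[Tuple[str, float], ...] = DEFAULT_CONDITIONS
    strokes_per_sprint: int = 4
    fs_hz: float = 256.0
    #: fraction of the steady-state cadence deficit closed within one sprint
    reach: float = 0.7
    #: geometric approach ratio between successive strokes
    approach_rho: float = 0.45
    rolling_start_rpm: float = 80.0
    #: fraction of each stroke period spent at the zero-torque trough
    trough_fraction: float = 0.2
    lead_in_s: float = 0.2

    def __post_init__(self):
        if self.t0_true <= 0:
            raise ValidationError("t0_true: must be positive")
        if self.rpmmax_true <= 0:
            raise ValidationError("rpmmax_true: must be positive")
        if self.torque_noise_sd < 0:
            raise ValidationError("torque_noise_sd: must be non-negative")
        if self.body_mass_kg <= 0:
            raise ValidationError("body_mass_kg: must be positive")
        if self.strokes_per_sprint < 3:
            raise ValidationError("strokes_per_sprint: need >= 3 for segmentation")
        if not (0 < self.reach < 1):
            raise ValidationError("reach: must lie in (0, 1)")
        if not (0 < self.approach_rho < 1):
            raise ValidationError("approach_rho: must lie in (0, 1)")
        if not (0 < self.trough_fraction < 0.5):
            raise ValidationError("trough_fraction: must lie in (0, 0.5)")
        for st, r in self.conditions:
            if st not in START_TYPES:
                raise ValidationError(f"conditions: unknown start type {st!r}")
            if not any(abs(r - a) < 1e-9 for a in ALLOWED_RESISTANCES):
                raise ValidationError(
                    f"conditions: resistance {r} not in {ALLOWED_RESISTANCES}"
                )


def cadence_trajectory(gt: CyclingGroundTruth, start_type: str, resistance: float
                       ) -> np.ndarray:
    """True per-stroke cadences (rpm) for one sprint condition.

    The steady-state cadence is where the rider's torque-cadence line meets
    the external load ``resistance * body mass``; a sprint closes ``reach``
    of the gap to it, strokes approaching geometrically with ratio
    ``approach_rho``.
    """

    load = resistance * gt.body_mass_kg
    if load >= gt.t0_true:
        raise GenerationError(
            f"external load {load:.1f} Nm exceeds maximal torque {gt.t0_true:.1f} Nm"
        )
    c_ss = gt.rpmmax_true * (1.0 - load / gt.t0_true)
    c0 = gt.rolling_start_rpm if start_type == ROLLING else 0.0
    if c_ss <= c0:
        raise GenerationError(
            "steady-state cadence below the start cadence; condition unrealisable"
        )
    target = c0 + (c_ss - c0) * gt.reach
    if target >= gt.rpmmax_true:
        raise GenerationError("requested cadence reaches rpmmax_true")
    k = np.arange(1, gt.strokes_per_sprint + 1)
    return target - (target - c0) * gt.approach_rho**k


def _build_trace(gt: CyclingGroundTruth, cadences: np.ndarray,
                 torques: np.ndarray) -> TorqueTrace:
    """Half-sine lobe train: one lobe per stroke, lobe mean == stroke torque."""
    fs = gt.fs_hz
    samples = [np.zeros(int(round(gt.lead_in_s * fs)))]
    for c, tq in zip(cadences, torques):
        period = 30.0 / c  # downstroke = half revolution
        n_k = max(4, int(round(period * fs)))
        gap_n = max(2, int(round(gt.trough_fraction * period * fs)))
        lobe_n = n_k - gap_n
        j = np.arange(lobe_n)
        lobe = max(tq, 0.0) * (math.pi / 2.0) * np.sin(math.pi * (j + 0.5) / lobe_n)
        samples.append(np.zeros(gap_n))
        samples.append(lobe)
    samples.append(np.zeros(max(2, int(round(0.1 * fs)))))
    torque = np.concatenate(samples)
    time = np.arange(len(torque)) / fs
    return TorqueTrace(time_s=time, torque_nm=torque, fs_hz=fs)


def generate_sprint_session(gt: CyclingGroundTruth, seed: int) -> SprintSession:
    """Generate one five-sprint session (traces + per-stroke summaries).

    Per-stroke mean torques are drawn from the torque-cadence line with
    Gaussian noise; per-stroke power is ``T * c * 2*pi/60``; the 256-Hz
    trace realises each stroke as a half-sine lobe whose mean equals the
    stroke's (noisy) mean torque. Deterministic given ``(gt, seed)``.
    """

    rng = np.random.default_rng(seed)
    trials = []
    for start_type, resistance in gt.conditions:
        cadences = cadence_trajectory(gt, start_type, resistance)
        line = gt.t0_true * (1.0 - cadences / gt.rpmmax_true)
        torques = line + rng.normal(0.0, gt.torque_noise_sd, size=len(cadences))
        torques = np.maximum(torques, 1e-6)
        strokes = [
            StrokeSummary(
                stroke_index=k + 1,
                mean_torque_nm=float(tq),
                cadence_rpm=float(c),
                power_w=float(tq * c * RPM_TO_RAD_S),
            )
            for k, (c, tq) in enumerate(zip(cadences, torques))
        ]
        trials.append(
            SprintTrial(
                start_type=start_type,
                resistance_nm_per_kg=resistance,
                strokes=strokes,
                trace=_build_trace(gt, cadences, torques),
            )
        )
    return SprintSession(trials=trials, body_mass_kg=gt.body_mass_kg)


@dataclass
class CohortSpec:
    """Population parameters for a paired pre/post cohort.

    Per metric: pre mean/SD, an additive true change at post, and
    optionally a post SD (defaults to the pre SD). ``prepost_corr`` is the
    within-participant correlation between pre and post values; paired
    training studies are strongly correlated (default 0.85), while 0 gives
    two independent groups.
    """

    n_participants: int = 14
    pre_means: Dict[str, float] = field(default_factory=dict)
    pre_sds: Dict[str, float] = field(default_factory=dict)
    changes: Dict[str, float] = field(default_factory=dict)
    post_sds: Optional[Dict[str, float]] = None
    prepost_corr: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValidationError("n_participants: must be >= 2")
        if not (-1.0 <= self.prepost_corr <= 1.0):
            raise ValidationError("prepost_corr: must lie in [-1, 1]")
        for m, sd in self.pre_sds.items():
            if sd <= 0:
                raise ValidationError(f"pre_sds[{m!r}]: must be positive")
        if set(self.pre_means) != set(self.pre_sds) or set(self.pre_means) != set(
            self.changes
        ):
            raise ValidationError(
                "pre_means/pre_sds/changes: must cover the same metrics"
            )


def generate_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, dict]:
    """Draw a paired pre/post metric table plus its ground-truth record.

    Returns a tidy frame with columns ``participant, timepoint, metric,
    value`` and a dict of the true population parameters used.
    """

    rng = np.random.default_rng(spec.seed)
    rho = spec.prepost_corr
    rows = []
    for metric in spec.pre_means:
        mu = spec.pre_means[metric]
        sd = spec.pre_sds[metric]
        delta = spec.changes[metric]
        sd_post = (spec.post_sds or {}).get(metric, sd)
        z1 = rng.normal(size=spec.n_participants)
        z2 = rng.normal(size=spec.n_participants)
        pre = mu + sd * z1
        post = mu + delta + sd_post * (rho * z1 + math.sqrt(1 - rho**2) * z2)
        for i in range(spec.n_participants):
            pid = f"P{i + 1:02d}"
            rows.append((pid, "pre", metric, float(pre[i])))
            rows.append((pid, "post", metric, float(post[i])))
    table = pd.DataFrame(rows, columns=["participant", "timepoint", "metric", "value"])
    truth = {
        "n_participants": spec.n_participants,
        "pre_means": dict(spec.pre_means),
        "pre_sds": dict(spec.pre_sds),
        "changes": dict(spec.changes),
        "post_sds": {
            m: (spec.post_sds or {}).get(m, spec.pre_sds[m]) for m in spec.pre_means
        },
        "prepost_corr": rho,
    }
    return table, truth
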