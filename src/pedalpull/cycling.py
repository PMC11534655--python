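"""Sprint-cycling crank-torque analysis.

Covers four stages:

1. segmentation of a continuous crank-torque trace into downstroke lobes
   (one rise-and-fall of total crank torque per half revolution);
2. rate of torque development (RTD) metrics on individual downstrokes,
   reusing the IMTP onset/band/window machinery with torque substituting
   force — by convention RTD is reported as the average of downstrokes 2
   and 3 of the 0.6 Nm/kg stationary sprint, the strokes where torque is
   near-maximal and the rise is slow enough to resolve;
3. observed session peaks: peak power output (PPO), peak cadence and peak
   torque over all downstrokes of all sprints;
4. torque-cadence (linear) and power-cadence (zero-intercept cubic)
   profile fits, yielding the extrapolated intercepts T0 and RPMmax and
   the interpolated apex Pmax at RPMopt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import (
    EXPLOSIVE_1S,
    RPM_TO_RAD_S,
    STATIONARY,
    AnalysisError,
    CyclingMetrics,
    ForceTimeTrial,
    ProfileFit,
    SprintSession,
    SprintTrial,
    StrokeSummary,
    TorqueTrace,
)
from . import imtp

RTD_FIELDS = ("rtd_0_100", "rtd_0_200", "rtd_avg", "rtd_peak")

#: resistance (Nm per kg body mass) of the sprint used for RTD extraction
RTD_RESISTANCE = 0.6
#: 1-based downstroke numbers averaged for RTD reporting
RTD_STROKES = (2, 3)


@dataclass
class Downstroke:
    """One segmented torque lobe with surrounding trough context."""

    index: int  # 1-based, temporal order
    trace: TorqueTrace
    lobe_start: int
    lobe_end: int  # exclusive
    ctx_start: int
    ctx_end: int  # exclusive

    @property
    def lobe_torque(self) -> np.ndarray:
        return self.trace.torque_nm[self.lobe_start : self.lobe_end]

    @property
    def mean_torque_nm(self) -> float:
        # The bounding trough samples mark dead centre, not the propulsive
        # phase; exclude samples sitting at the lobe's minimum level.
        lt = self.lobe_torque
        core = lt[lt > np.min(lt) + 1e-12]
        return float(np.mean(core)) if len(core) else float(np.mean(lt))

    @property
    def peak_torque_nm(self) -> float:
        return float(np.max(self.lobe_torque))

    @property
    def duration_s(self) -> float:
        return (self.lobe_end - self.lobe_start) / self.trace.fs_hz


def segment_downstrokes(
    trace: TorqueTrace,
    rel_threshold: float = 0.1,
    min_lobe_s: float = 0.03,
    min_strokes: int = 3,
) -> List[Downstroke]:
    """Split a crank-torque trace into downstroke lobes.

    Candidate lobes are contiguous runs where torque exceeds
    ``rel_threshold`` times the trace maximum; each run is then extended
    outward to the adjacent local minima (the inter-lobe troughs), so lobe
    boundaries land on the true rise start and fall end. Runs shorter than
    ``min_lobe_s`` are treated as noise blips and discarded.
    """

    tq = trace.torque_nm
    peak = float(np.max(tq)) if len(tq) else 0.0
    if peak <= 0:
        raise AnalysisError("trace contains no positive torque; cannot segment")
    above = tq > rel_threshold * peak
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) + 1 for e in edges if above[e]]
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(tq))

    min_lobe_n = max(1, int(round(min_lobe_s * trace.fs_hz)))
    regions = [(s, e) for s, e in zip(starts, ends) if e - s >= min_lobe_n]
    if len(regions) < min_strokes:
        raise AnalysisError(
            f"found {len(regions)} downstroke lobes; need >= {min_strokes}"
        )

    # walk each region edge down the slope to the true trough
    lobes = []
    for s, e in regions:
        while s > 0 and tq[s - 1] < tq[s]:
            s -= 1
        while e < len(tq) and tq[e] < tq[e - 1]:
            e += 1
        lobes.append((s, e))

    strokes = []
    for k, (s, e) in enumerate(lobes):
        ctx_start = lobes[k - 1][1] if k > 0 else 0
        ctx_end = lobes[k + 1][0] if k + 1 < len(lobes) else len(tq)
        strokes.append(
            Downstroke(
                index=k + 1,
                trace=trace,
                lobe_start=s,
                lobe_end=e,
                ctx_start=ctx_start,
                ctx_end=max(ctx_end, e),
            )
        )
    return strokes


def rtd_downstroke(
    ds: Downstroke,
    baseline_s: float = 0.030,
    k_sd: float = 3.0,
    window_ms: float = 20.0,
) -> dict:
    """RTD metrics for one downstroke, via the IMTP machinery.

    The segment (trough context + lobe) is wrapped as a force-time trial
    with torque standing in for force and the ``baseline_s`` of trough
    preceding the rise as the quiet baseline. Band metrics whose window
    runs past the end of the segment are returned as NaN (flagged missing).
    """

    fs = ds.trace.fs_hz
    t = ds.trace.time_s[ds.ctx_start : ds.ctx_end]
    tq = ds.trace.torque_nm[ds.ctx_start : ds.ctx_end]
    lobe_t0 = ds.trace.time_s[ds.lobe_start]
    base_start = max(t[0], lobe_t0 - baseline_s)
    trial = ForceTimeTrial(
        time_s=t,
        force_n=tq,
        fs_hz=fs,
        trial_type=EXPLOSIVE_1S,
        baseline_window_s=(base_start, max(base_start + 2.0 / fs, lobe_t0 - 1.0 / fs)),
        min_duration_s=0.05,
    )
    onset = imtp.detect_onset(
        trial, k_sd=k_sd, extremum_lookback_s=0.03, min_baseline_samples=3
    )
    out = {
        "onset_time_s": onset.time_s,
        "peak_torque_nm": float(np.max(tq) - onset.baseline_mean),
        "rtd_avg": imtp.rfd_avg(trial, onset),
        "rtd_peak": imtp.rfd_peak(trial, onset, window_ms),
    }
    for name, band in (("rtd_0_100", 100.0), ("rtd_0_200", 200.0)):
        try:
            out[name] = imtp.rfd_band(trial, onset, band)
        except AnalysisError:
            out[name] = float("nan")
    return out


def rtd_sprint(
    trial: SprintTrial,
    strokes: Sequence[int] = RTD_STROKES,
    k_sd: float = 3.0,
    window_ms: float = 20.0,
) -> dict:
    """Averaged RTD metrics over the prescribed downstrokes of the 0.6 sprint."""

    if trial.start_type != STATIONARY or abs(
        trial.resistance_nm_per_kg - RTD_RESISTANCE
    ) > 1e-9:
        raise AnalysisError(
            "RTD defined only for the 0.6 Nm·kg⁻¹ stationary sprint"
        )
    if trial.trace is None:
        raise AnalysisError("RTD requires the continuous torque trace")
    segments = segment_downstrokes(trial.trace)
    if max(strokes) > len(segments):
        raise AnalysisError(
            f"sprint has {len(segments)} downstrokes; need stroke {max(strokes)}"
        )
    per_stroke = [
        rtd_downstroke(segments[i - 1], k_sd=k_sd, window_ms=window_ms)
        for i in strokes
    ]
    return {
        f: float(np.mean([p[f] for p in per_stroke])) for f in RTD_FIELDS
    }


def observed_session_peaks(session: SprintSession) -> dict:
    """Highest observed power, cadence and torque across all sprints.

    Power and cadence maxima come from the per-stroke records. Peak torque
    is the maximum instantaneous crank torque over the continuous traces
    when traces are available (a downstroke's torque crest sits well above
    its mean), falling back to the maximum per-stroke mean torque.
    """

    powers, cadences, stroke_torques, trace_torques = [], [], [], []
    for tr in session.trials:
        for s in tr.strokes:
            powers.append(s.power_w)
            cadences.append(s.cadence_rpm)
            stroke_torques.append(s.mean_torque_nm)
        if tr.trace is not None:
            trace_torques.append(float(np.max(tr.trace.torque_nm)))
    if not powers:
        raise AnalysisError("session contains no stroke records")
    ppo = float(np.max(powers))
    return {
        "ppo_w": ppo,
        "ppo_per_bm": ppo / session.body_mass_kg,
        "rpm_peak": float(np.max(cadences)),
        "t_peak_nm": float(np.max(trace_torques))
        if trace_torques
        else float(np.max(stroke_torques)),
    }


@dataclass
class TorqueCadenceFit:
    """OLS line T(c) = t0 + slope*c with its extrapolated intercepts."""

    slope: float
    t0_nm: float
    rpmmax_rpm: float
    r2: float
    residual_sd: float
    n_points: int


@dataclass
class PowerCadenceFit:
    """Zero-intercept cubic P(c) = a1*c + a2*c^2 + a3*c^3 and its apex."""

    coeffs: tuple
    pmax_w: float
    rpmopt_rpm: float
    r2: float
    residual_sd: float
    n_points: int


def _strokes_xy(strokes: Sequence[StrokeSummary], attr: str):
    c = np.array([s.cadence_rpm for s in strokes], dtype=float)
    y = np.array([getattr(s, attr) for s in strokes], dtype=float)
    return c, y


def fit_torque_cadence(strokes: Sequence[StrokeSummary]) -> TorqueCadenceFit:
    """Fit the linear torque-cadence profile; T0 and RPMmax are its intercepts."""

    c, tq = _strokes_xy(strokes, "mean_torque_nm")
    if len(np.unique(c)) < 3:
        raise AnalysisError("need >= 3 strokes with distinct cadences")
    res = sps.linregress(c, tq)
    if res.slope >= 0:
        raise AnalysisError("non-decreasing torque-cadence profile")
    t0 = float(res.intercept)
    rpmmax = float(-res.intercept / res.slope)
    if not np.isfinite(rpmmax) or rpmmax <= 0:
        raise AnalysisError("non-physical extrapolated maximal cadence")
    pred = res.intercept + res.slope * c
    resid = tq - pred
    return TorqueCadenceFit(
        slope=float(res.slope),
        t0_nm=t0,
        rpmmax_rpm=rpmmax,
        r2=float(res.rvalue**2),
        residual_sd=float(np.std(resid, ddof=2)) if len(c) > 2 else 0.0,
        n_points=len(c),
    )


def fit_power_cadence(
    strokes: Sequence[StrokeSummary], apex_cadence_factor: float = 1.2
) -> PowerCadenceFit:
    """Fit the power-cadence cubic with its y-intercept pinned at zero.

    The apex (theoretical peak power Pmax at optimal cadence RPMopt) is the
    stationary point of the fitted cubic within ``(0, apex_cadence_factor *
    max observed cadence)`` with the greatest fitted power.
    """

    c, p = _strokes_xy(strokes, "power_w")
    if len(np.unique(c)) < 4:
        raise AnalysisError("need >= 4 strokes with distinct cadences")
    scale = float(np.max(c))
    u = c / scale
    X = np.column_stack([u, u**2, u**3])
    b, *_ = np.linalg.lstsq(X, p, rcond=None)
    if not np.all(np.isfinite(b)):
        raise AnalysisError("degenerate design matrix for the power-cadence fit")
    a = (b[0] / scale, b[1] / scale**2, b[2] / scale**3)

    pred = X @ b
    resid = p - pred
    ss_tot = float(np.sum((p - np.mean(p)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    # stationary points of a1*c + a2*c^2 + a3*c^3
    da = np.array([3 * a[2], 2 * a[1], a[0]])
    lead_scale = max(abs(a[0]) / scale**2, 1e-300)
    if abs(da[0]) < 1e-12 * lead_scale:
        roots = np.array([-a[0] / (2 * a[1])]) if a[1] != 0 else np.array([])
    else:
        roots = np.roots(da)
    cand = [
        float(r.real)
        for r in np.atleast_1d(roots)
        if abs(r.imag) < 1e-8 * scale and 0 < r.real < apex_cadence_factor * scale
    ]
    if not cand:
        raise AnalysisError("no interior apex in the fitted power-cadence curve")
    powers_at = [a[0] * x + a[1] * x**2 + a[2] * x**3 for x in cand]
    i_best = int(np.argmax(powers_at))
    return PowerCadenceFit(
        coeffs=tuple(float(x) for x in a),
        pmax_w=float(powers_at[i_best]),
        rpmopt_rpm=float(cand[i_best]),
        r2=r2,
        residual_sd=float(np.std(resid, ddof=3)) if len(c) > 3 else 0.0,
        n_points=len(c),
    )


def select_profile_strokes(trial: SprintTrial) -> List[StrokeSummary]:
    """Acceleration-phase strokes: all up to and including the fastest stroke.

    Strokes after a sprint's cadence maximum belong to the fatigue/plateau
    phase and would bias the profile fits; they are excluded.
    """

    strokes = sorted(trial.strokes, key=lambda s: s.stroke_index)
    if not strokes:
        return []
    i_max = int(np.argmax([s.cadence_rpm for s in strokes]))
    return strokes[: i_max + 1]


def profile_session(
    session: SprintSession,
    expected_conditions: Optional[Sequence[tuple]] = None,
    k_sd: float = 3.0,
    rtd_window_ms: float = 20.0,
) -> CyclingMetrics:
    """Assemble the full cycling summary for one session.

    Combines observed peaks, RTD from the 0.6 Nm/kg stationary sprint, and
    the torque-cadence / power-cadence profile fits over the acceleration-
    phase strokes of every sprint. Missing conditions degrade gracefully
    with a warning (RTD fields become NaN without the 0.6 sprint).
    """

    if expected_conditions is not None:
        have = {(t.start_type, round(t.resistance_nm_per_kg, 3)) for t in session.trials}
        missing = [c for c in expected_conditions if (c[0], round(c[1], 3)) not in have]
        if missing:
            warnings.warn(f"session missing sprint conditions: {missing}", stacklevel=2)

    peaks = observed_session_peaks(session)

    rtd = {f: float("nan") for f in RTD_FIELDS}
    rtd_trial = session.find_trial(STATIONARY, RTD_RESISTANCE)
    if rtd_trial is not None and rtd_trial.trace is not None:
        rtd = rtd_sprint(rtd_trial, k_sd=k_sd, window_ms=rtd_window_ms)
    else:
        warnings.warn(
            "no 0.6 Nm/kg stationary sprint with a torque trace; RTD left empty",
            stacklevel=2,
        )

    strokes: List[StrokeSummary] = []
    for tr in session.trials:
        strokes.extend(select_profile_strokes(tr))
    tc = fit_torque_cadence(strokes)
    pc = fit_power_cadence(strokes)

    fit = ProfileFit(
        tc_slope=tc.slope,
        tc_intercept=tc.t0_nm,
        tc_r2=tc.r2,
        pc_coeffs=pc.coeffs,
        pc_r2=pc.r2,
        n_points=len(strokes),
        tc_residual_sd=tc.residual_sd,
        pc_residual_sd=pc.residual_sd,
    )
    return CyclingMetrics(
        **peaks,
        **rtd,
        t0_nm=tc.t0_nm,
        pmax_w=pc.pmax_w,
        rpmmax_rpm=tc.rpmmax_rpm,
        rpmopt_rpm=pc.rpmopt_rpm,
        tc_r2=tc.r2,
        pc_r2=pc.r2,
        n_points=len(strokes),
        fit=fit,
    )
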