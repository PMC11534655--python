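"""IMTP force-time analysis.

Derives the standard isometric mid-thigh pull metrics from a raw force-time
record: automated force onset, net peak force (PF), fixed-band rates of
force development (RFD 0-100 ms and 0-200 ms), average RFD (onset to PF)
and peak RFD (fastest 20-ms window). No filtering or smoothing is applied
at any stage; the detectors operate on the raw signal.

Force onset follows the verbal rule used in manual analysis — the last
peak/trough before the signal deflects away from baseline noise — made
automatic: find the first sustained crossing of ``baseline mean + k*SD``,
then backtrack to the last local extremum of the raw signal within a short
lookback window.

The same machinery is reused for crank-torque downstrokes (with torque
substituting force); see :mod:`pedalpull.cycling`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    EXPLOSIVE_1S,
    MAX_5S,
    AnalysisError,
    ForceTimeTrial,
    IMTPMetrics,
    OnsetNotFoundError,
    ValidationError,
)


@dataclass
class Onset:
    """Detected signal onset: sample index, time and raw signal value."""

    index: int
    time_s: float
    force_n: float
    baseline_mean: float
    baseline_sd: float


def _baseline_stats(trial: ForceTimeTrial, min_samples: int):
    sl = trial.baseline_slice()
    seg = trial.force_n[sl]
    if len(seg) < min_samples:
        raise AnalysisError(
            f"baseline window has {len(seg)} samples; need >= {min_samples}"
        )
    return float(np.mean(seg)), float(np.std(seg, ddof=1)), sl


def detect_onset(
    trial: ForceTimeTrial,
    k_sd: float = 3.0,
    extremum_lookback_s: float = 0.05,
    sustain_s: float = 0.010,
    min_baseline_samples: int = 100,
) -> Onset:
    """Detect force onset on a raw trial.

    The first sample whose force exceeds ``baseline mean + k_sd * SD`` and
    stays above that threshold for at least ``sustain_s`` marks the
    deflection from baseline noise; the onset is the last local extremum
    (peak or trough) of the raw signal within ``extremum_lookback_s``
    before that crossing, or the crossing sample itself when the preceding
    signal is flat.

    Raises
    ------
    OnsetNotFoundError
        If no sustained crossing exists (e.g. a constant signal).
    """

    mu, sd, bsl = _baseline_stats(trial, min_baseline_samples)
    f = trial.force_n
    fs = trial.fs_hz
    sustain_n = max(1, int(round(sustain_s * fs)))

    start = bsl.stop
    threshold = mu + k_sd * sd
    above = f > threshold
    cross = _first_sustained(above, start, sustain_n)
    if cross is None:
        raise OnsetNotFoundError("no onset detected")

    # A rise leaking into the baseline window biases mu/sd upward; shrink the
    # window to end safely before the crossing and redo the detection once.
    guard = int(round(0.05 * fs))
    if bsl.stop > cross and cross - guard - bsl.start >= min_baseline_samples:
        warnings.warn(
            "baseline window overlaps the detected rise; shifting its end earlier",
            stacklevel=2,
        )
        mu = float(np.mean(f[bsl.start : cross - guard]))
        sd = float(np.std(f[bsl.start : cross - guard], ddof=1))
        threshold = mu + k_sd * sd
        cross2 = _first_sustained(f > threshold, bsl.start, sustain_n)
        if cross2 is not None:
            cross = cross2

    lookback_n = max(1, int(round(extremum_lookback_s * fs)))
    lo = max(1, cross - lookback_n)
    idx = cross
    # local extremum = strict sign change of the first difference
    found = False
    for j in range(cross - 1, lo - 1, -1):
        left = f[j] - f[j - 1]
        right = f[j + 1] - f[j]
        if (left > 0 and right < 0) or (left < 0 and right > 0):
            idx = j
            found = True
            break
    if not found:
        # flat pre-rise signal (no noise extrema): walk down the monotone
        # rise to its corner, the last sample before the deflection
        j = cross
        while j > lo and f[j - 1] < f[j]:
            j -= 1
        idx = j
    return Onset(
        index=idx,
        time_s=float(trial.time_s[idx]),
        force_n=float(f[idx]),
        baseline_mean=mu,
        baseline_sd=sd,
    )


def _first_sustained(above: np.ndarray, start: int, sustain_n: int):
    """First index >= start where `above` holds for sustain_n consecutive samples."""
    n = len(above)
    run = 0
    first = None
    for i in range(start, n):
        if above[i]:
            if run == 0:
                first = i
            run += 1
            if run >= sustain_n:
                return first
        else:
            run = 0
    return None


def peak_force(trial: ForceTimeTrial, onset: Onset):
    """Net peak force (max force minus baseline mean) and time from onset to it.

    The baseline mean embodies body weight plus posture load on the plate, so
    the subtraction nets out the participant's body mass in force units. With
    tied maxima the earliest sample wins.
    """

    f = trial.force_n
    i_pk = int(np.argmax(f))  # argmax returns the first of tied maxima
    bsl = trial.baseline_slice()
    if bsl.start <= i_pk < bsl.stop:
        raise AnalysisError("inverted trial: maximum force occurs in the baseline window")
    net = float(f[i_pk] - onset.baseline_mean)
    if net <= 0:
        raise AnalysisError("inverted trial: no force rise above baseline")
    return net, float(trial.time_s[i_pk] - trial.time_s[onset.index]), i_pk


def rfd_band(trial: ForceTimeTrial, onset: Onset, band_end_ms: float) -> float:
    """RFD over a fixed band from onset: (F(onset+band) - F(onset)) / band.

    The band endpoint is snapped to the nearest sample of the uniform grid;
    the divisor is the nominal band duration.
    """

    j = onset.index + int(round(band_end_ms / 1000.0 * trial.fs_hz))
    if j >= trial.n_samples:
        raise AnalysisError(
            f"record too short for a {band_end_ms:g}-ms band after onset"
        )
    return float(
        (trial.force_n[j] - trial.force_n[onset.index]) / (band_end_ms / 1000.0)
    )


def rfd_avg(trial: ForceTimeTrial, onset: Onset) -> float:
    """Average RFD: force change from onset to PF over the elapsed time."""

    f = trial.force_n
    i_pk = int(np.argmax(f))
    dt = float(trial.time_s[i_pk] - trial.time_s[onset.index])
    if dt <= 0:
        raise AnalysisError("peak coincides with onset; average RFD undefined")
    return float((f[i_pk] - f[onset.index]) / dt)


def rfd_peak(trial: ForceTimeTrial, onset: Onset, window_ms: float = 20.0) -> float:
    """Peak RFD: fastest force change over any ``window_ms`` window.

    Windows advance one sample at a time from onset to the end of the
    record; the window length is snapped to the sample grid and the divisor
    is the nominal window duration.
    """

    w = int(round(window_ms / 1000.0 * trial.fs_hz))
    if w < 1:
        raise AnalysisError("window shorter than one sample interval")
    seg = trial.force_n[onset.index :]
    if len(seg) <= w:
        raise AnalysisError(f"record shorter than one {window_ms:g}-ms window")
    deltas = seg[w:] - seg[:-w]
    return float(np.max(deltas) / (window_ms / 1000.0))


def analyze_imtp_trial(
    trial: ForceTimeTrial,
    k_sd: float = 3.0,
    extremum_lookback_s: float = 0.05,
    rfd_window_ms: float = 20.0,
    min_baseline_samples: int = 100,
) -> IMTPMetrics:
    """Run the full IMTP metric extraction on one trial.

    All metrics are computed for every trial; ``canonical_pf`` and
    ``canonical_rfd`` record whether each family came from the trial type
    the testing convention prescribes (PF from 5-s maximal trials, RFD from
    1-s explosive trials).
    """

    onset = detect_onset(
        trial,
        k_sd=k_sd,
        extremum_lookback_s=extremum_lookback_s,
        min_baseline_samples=min_baseline_samples,
    )
    pf, t_pf, _ = peak_force(trial, onset)
    metrics = IMTPMetrics(
        onset_time_s=onset.time_s,
        onset_force_n=onset.force_n,
        peak_force_n=pf,
        time_to_pf_s=t_pf,
        rfd_0_100=rfd_band(trial, onset, 100.0),
        rfd_0_200=rfd_band(trial, onset, 200.0),
        rfd_avg=rfd_avg(trial, onset),
        rfd_peak=rfd_peak(trial, onset, rfd_window_ms),
        trial_type=trial.trial_type,
        canonical_pf=trial.trial_type == MAX_5S,
        canonical_rfd=trial.trial_type == EXPLOSIVE_1S,
    )
    return metrics


#: metric used to rank trials when choosing the best ones, per set type
_RANK_KEY = {MAX_5S: "peak_force_n", EXPLOSIVE_1S: "rfd_peak"}


def aggregate_best_trials(
    trials: list, set_type: str, n_best: int = 3
) -> IMTPMetrics:
    """Mean of each metric over the ``n_best`` best trials of a set.

    5-s sets rank by net peak force, 1-s explosive sets by peak RFD. Trials
    whose ranking metric is non-finite are excluded; an informative error is
    raised when fewer than ``n_best`` valid trials remain.
    """

    if set_type not in _RANK_KEY:
        raise ValidationError(f"set_type: must be one of {tuple(_RANK_KEY)}")
    key = _RANK_KEY[set_type]
    valid, excluded = [], []
    for i, m in enumerate(trials):
        if np.isfinite(getattr(m, key)):
            valid.append(m)
        else:
            excluded.append(i)
    if len(valid) < n_best:
        raise AnalysisError(
            f"only {len(valid)} valid trials (need {n_best}); "
            f"excluded trial indices: {excluded}"
        )
    best = sorted(valid, key=lambda m: getattr(m, key), reverse=True)[:n_best]
    agg = {
        f: float(np.mean([getattr(m, f) for m in best]))
        for f in IMTPMetrics.METRIC_FIELDS
    }
    return IMTPMetrics(
        **agg,
        trial_type=set_type,
        canonical_pf=set_type == MAX_5S,
        canonical_rfd=set_type == EXPLOSIVE_1S,
    )
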