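"""Crank-torque analysis: segmentation, RTD, peaks, profile fits."""

import math
import warnings

import numpy as np
import pytest

from pedalpull import (
    AnalysisError,
    CyclingGroundTruth,
    SprintTrial,
    StrokeSummary,
    TorqueTrace,
    generate_sprint_session,
    profile_session,
)
from pedalpull.cycling import (
    fit_power_cadence,
    fit_torque_cadence,
    observed_session_peaks,
    rtd_downstroke,
    rtd_sprint,
    segment_downstrokes,
    select_profile_strokes,
)
from pedalpull.synthetic import DEFAULT_CONDITIONS
from pedalpull.types import RPM_TO_RAD_S, SprintSession


def half_sine_train(n_lobes=6, lobe_n=80, gap_n=20, amp=100.0, fs=256.0):
    parts, bounds = [np.zeros(gap_n)], []
    for k in range(n_lobes):
        start = sum(len(p) for p in parts)
        j = np.arange(lobe_n)
        parts.append(amp * np.sin(math.pi * (j + 0.5) / lobe_n))
        parts.append(np.zeros(gap_n))
        bounds.append((start, start + lobe_n))
    tq = np.concatenate(parts)
    return TorqueTrace(np.arange(len(tq)) / fs, tq, fs), bounds


def strokes_on_line(cadences, t0=200.0, rpmmax=200.0):
    return [
        StrokeSummary(
            stroke_index=i + 1,
            mean_torque_nm=t0 * (1 - c / rpmmax),
            cadence_rpm=c,
            power_w=t0 * (1 - c / rpmmax) * c * RPM_TO_RAD_S,
        )
        for i, c in enumerate(cadences)
    ]


class TestSegmentation:
    def test_six_lobe_train_found_at_true_boundaries(self):
        trace, bounds = half_sine_train(n_lobes=6)
        segs = segment_downstrokes(trace)
        assert len(segs) == 6
        for seg, (s, e) in zip(segs, bounds):
            assert abs(seg.lobe_start - s) <= 1
            assert abs(seg.lobe_end - e) <= 1

    def test_all_zero_trace_rejected(self):
        trace = TorqueTrace(np.arange(500) / 256.0, np.zeros(500), 256.0)
        with pytest.raises(AnalysisError):
            segment_downstrokes(trace)

    def test_too_few_lobes_rejected(self):
        trace, _ = half_sine_train(n_lobes=2)
        with pytest.raises(AnalysisError):
            segment_downstrokes(trace)

    def test_segment_means_match_generator_stroke_torques(self, noiseless_session):
        _, session = noiseless_session
        for trial in session.trials:
            segs = segment_downstrokes(trial.trace)
            assert len(segs) == len(trial.strokes)
            for seg, stroke in zip(segs, trial.strokes):
                assert seg.mean_torque_nm == pytest.approx(
                    stroke.mean_torque_nm, rel=0.01
                )


class TestRTD:
    def test_triangular_lobe_band_arithmetic(self):
        # triangular lobes rising 60 Nm in 200 ms at 500 Hz: the first lobe
        # sample (the detected onset) to the sample 100 steps later spans
        # exactly 60 Nm, so RTD_0-200 = 60 / 0.2 = 300 Nm/s.
        fs, slope_per_sample = 500.0, 0.6
        rise = slope_per_sample * np.arange(1, 102)  # 0.6 .. 60.6
        fall = np.linspace(60.6, 0.0, 102)[1:]
        lobe = np.concatenate([rise, fall])
        tq = np.concatenate([np.zeros(50)] + [np.concatenate([lobe, np.zeros(50)])] * 3)
        trace = TorqueTrace(np.arange(len(tq)) / fs, tq, fs)
        segs = segment_downstrokes(trace)
        out = rtd_downstroke(segs[1])
        assert out["rtd_0_200"] == pytest.approx(300.0, rel=1e-9)
        assert out["rtd_avg"] == pytest.approx(300.0, rel=1e-9)

    def test_shares_the_imtp_machinery_on_identical_series(self):
        # running the IMTP operations on the wrapped segment reproduces RTD
        from pedalpull import detect_onset, rfd_band, rfd_peak
        from pedalpull.types import ForceTimeTrial

        trace, _ = half_sine_train(n_lobes=3, lobe_n=120, gap_n=30, amp=80.0)
        seg = segment_downstrokes(trace)[1]
        out = rtd_downstroke(seg)
        t = trace.time_s[seg.ctx_start : seg.ctx_end]
        tq = trace.torque_nm[seg.ctx_start : seg.ctx_end]
        lobe_t0 = trace.time_s[seg.lobe_start]
        trial = ForceTimeTrial(
            t, tq, trace.fs_hz, "explosive_1s",
            (lobe_t0 - 0.030, lobe_t0 - 1.0 / trace.fs_hz), min_duration_s=0.05,
        )
        onset = detect_onset(trial, min_baseline_samples=3, extremum_lookback_s=0.03)
        assert out["rtd_0_100"] == rfd_band(trial, onset, 100.0)
        assert out["rtd_peak"] == rfd_peak(trial, onset)

    def test_rtd_sprint_averages_downstrokes_2_and_3(self, noiseless_session):
        _, session = noiseless_session
        trial = session.find_trial("stationary", 0.6)
        out = rtd_sprint(trial)
        segs = segment_downstrokes(trial.trace)
        d2, d3 = rtd_downstroke(segs[1]), rtd_downstroke(segs[2])
        for f in ("rtd_0_100", "rtd_avg", "rtd_peak"):
            assert out[f] == pytest.approx((d2[f] + d3[f]) / 2.0, rel=1e-12)

    def test_rtd_rejects_other_conditions(self, noiseless_session):
        _, session = noiseless_session
        rolling = session.find_trial("rolling", 0.2)
        with pytest.raises(AnalysisError, match="0.6"):
            rtd_sprint(rolling)


class TestPeaks:
    def test_relative_ppo_arithmetic(self):
        strokes = [StrokeSummary(1, 100.0, 113.24, 1186.0)]
        session = SprintSession(
            trials=[SprintTrial("stationary", 0.2, strokes)], body_mass_kg=77.0
        )
        peaks = observed_session_peaks(session)
        assert peaks["ppo_per_bm"] == pytest.approx(1186.0 / 77.0)
        assert peaks["t_peak_nm"] == 100.0  # no trace: max stroke mean torque

    def test_generator_session_maxima_match_stroke_records(self, noiseless_session):
        _, session = noiseless_session
        peaks = observed_session_peaks(session)
        all_strokes = [s for tr in session.trials for s in tr.strokes]
        assert peaks["ppo_w"] == max(s.power_w for s in all_strokes)
        assert peaks["rpm_peak"] == max(s.cadence_rpm for s in all_strokes)
        # with traces present, peak torque is the instantaneous lobe crest
        assert peaks["t_peak_nm"] == max(
            float(np.max(tr.trace.torque_nm)) for tr in session.trials
        )

    def test_empty_session_rejected(self):
        session = SprintSession(
            trials=[SprintTrial("stationary", 0.2, [])], body_mass_kg=77.0
        )
        with pytest.raises(AnalysisError):
            observed_session_peaks(session)


class TestTorqueCadenceFit:
    def test_exact_line_recovered(self):
        fit = fit_torque_cadence(strokes_on_line([40, 80, 120, 160]))
        assert fit.t0_nm == pytest.approx(200.0, rel=1e-9)
        assert fit.rpmmax_rpm == pytest.approx(200.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_rejected(self):
        with pytest.raises(AnalysisError):
            fit_torque_cadence(strokes_on_line([40, 80]))

    def test_rising_profile_rejected(self):
        strokes = [
            StrokeSummary(i + 1, 10.0 + c, c, (10.0 + c) * c * RPM_TO_RAD_S)
            for i, c in enumerate([40.0, 80.0, 120.0])
        ]
        with pytest.raises(AnalysisError, match="non-decreasing"):
            fit_torque_cadence(strokes)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(30, 180, 12)
        tq = 180.0 - 0.8 * c + rng.normal(0, 4, 12)
        strokes = [
            StrokeSummary(i + 1, t, cc, t * cc * RPM_TO_RAD_S)
            for i, (cc, t) in enumerate(zip(c, tq))
        ]
        fit = fit_torque_cadence(strokes)
        X = np.column_stack([np.ones_like(c), c])
        beta = np.linalg.solve(X.T @ X, X.T @ tq)
        assert fit.t0_nm == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)


class TestPowerCadenceFit:
    def test_parabola_from_study_profile_parameters(self):
        # P(c) = (pi/30) * 165.2 * c * (1 - c/232.2): apex 1004.2 W at 116.1 rpm
        t0, rpmmax = 165.2, 232.2
        c = np.linspace(30, 190, 12)
        strokes = [
            StrokeSummary(
                i + 1, t0 * (1 - cc / rpmmax), cc,
                t0 * (1 - cc / rpmmax) * cc * RPM_TO_RAD_S,
            )
            for i, cc in enumerate(c)
        ]
        fit = fit_power_cadence(strokes)
        assert fit.rpmopt_rpm == pytest.approx(rpmmax / 2.0, rel=1e-6)
        assert fit.pmax_w == pytest.approx(math.pi * t0 * rpmmax / 120.0, rel=1e-6)

    def test_exact_cubic_apex_recovered(self):
        a1, a2, a3 = 20.0, -0.05, -2e-4
        c = np.linspace(20, 180, 10)
        p = a1 * c + a2 * c**2 + a3 * c**3
        strokes = [
            StrokeSummary(i + 1, pw / (cc * RPM_TO_RAD_S), cc, pw)
            for i, (cc, pw) in enumerate(zip(c, p))
        ]
        fit = fit_power_cadence(strokes)
        disc = math.sqrt((2 * a2) ** 2 - 4 * 3 * a3 * a1)
        roots = [(-2 * a2 + s * disc) / (2 * 3 * a3) for s in (1, -1)]
        apex = max(
            (r for r in roots if 0 < r < 1.2 * c.max()),
            key=lambda r: a1 * r + a2 * r**2 + a3 * r**3,
        )
        assert fit.rpmopt_rpm == pytest.approx(apex, rel=1e-6)

    def test_zero_intercept_by_construction(self, noiseless_session):
        _, session = noiseless_session
        strokes = [s for tr in session.trials for s in select_profile_strokes(tr)]
        fit = fit_power_cadence(strokes)
        a1, a2, a3 = fit.coeffs
        assert a1 * 0 + a2 * 0 + a3 * 0 == 0.0

    def test_monotone_power_has_no_interior_apex(self):
        c = np.linspace(20, 100, 8)
        p = 5.0 * c  # strictly increasing, stationary point nowhere
        strokes = [
            StrokeSummary(i + 1, pw / (cc * RPM_TO_RAD_S), cc, pw)
            for i, (cc, pw) in enumerate(zip(c, p))
        ]
        with pytest.raises(AnalysisError, match="apex"):
            fit_power_cadence(strokes)

    def test_stroke_order_invariance(self, noiseless_session):
        _, session = noiseless_session
        strokes = [s for tr in session.trials for s in select_profile_strokes(tr)]
        rng = np.random.default_rng(0)
        shuffled = list(strokes)
        rng.shuffle(shuffled)
        f1, f2 = fit_power_cadence(strokes), fit_power_cadence(shuffled)
        t1, t2 = fit_torque_cadence(strokes), fit_torque_cadence(shuffled)
        assert f1.pmax_w == pytest.approx(f2.pmax_w, rel=1e-12)
        assert t1.t0_nm == pytest.approx(t2.t0_nm, rel=1e-12)

    def test_torque_doubling_units(self, noiseless_session):
        _, session = noiseless_session
        strokes = [s for tr in session.trials for s in select_profile_strokes(tr)]
        doubled = [
            StrokeSummary(s.stroke_index, 2 * s.mean_torque_nm, s.cadence_rpm,
                          2 * s.power_w)
            for s in strokes
        ]
        tc1, tc2 = fit_torque_cadence(strokes), fit_torque_cadence(doubled)
        pc1, pc2 = fit_power_cadence(strokes), fit_power_cadence(doubled)
        assert tc2.t0_nm == pytest.approx(2 * tc1.t0_nm, rel=1e-9)
        assert tc2.rpmmax_rpm == pytest.approx(tc1.rpmmax_rpm, rel=1e-9)
        assert pc2.pmax_w == pytest.approx(2 * pc1.pmax_w, rel=1e-9)
        assert pc2.rpmopt_rpm == pytest.approx(pc1.rpmopt_rpm, rel=1e-9)


class TestProfileSession:
    def test_noiseless_session_reproduces_truth(self, noiseless_session):
        gt, session = noiseless_session
        m = profile_session(session, expected_conditions=DEFAULT_CONDITIONS)
        assert m.t0_nm == pytest.approx(gt.t0_true, rel=1e-6)
        assert m.rpmmax_rpm == pytest.approx(gt.rpmmax_true, rel=1e-6)
        assert m.rpmopt_rpm == pytest.approx(gt.rpmmax_true / 2.0, rel=0.005)
        assert m.pmax_w == pytest.approx(
            math.pi * gt.t0_true * gt.rpmmax_true / 120.0, rel=0.005
        )
        assert 0 <= m.tc_r2 <= 1 and 0 <= m.pc_r2 <= 1
        assert m.rpmopt_rpm < m.rpmmax_rpm

    def test_missing_rtd_sprint_warns_and_leaves_nan(self, noiseless_session):
        _, session = noiseless_session
        reduced = SprintSession(
            trials=[t for t in session.trials
                    if not (t.start_type == "stationary"
                            and t.resistance_nm_per_kg == 0.6)],
            body_mass_kg=session.body_mass_kg,
        )
        with pytest.warns(UserWarning):
            m = profile_session(reduced, expected_conditions=DEFAULT_CONDITIONS)
        assert math.isnan(m.rtd_0_100)
        assert math.isfinite(m.t0_nm)

    def test_determinism(self, noiseless_session):
        _, session = noiseless_session
        m1 = profile_session(session)
        m2 = profile_session(session)
        assert m1.as_dict() == m2.as_dict()
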