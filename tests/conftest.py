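import numpy as np
import pytest

from pedalpull import (
    CyclingGroundTruth,
    ForceTimeTrial,
    IMTPGroundTruth,
    generate_imtp_trial,
    generate_sprint_session,
)


def make_ramp_trial(
    baseline=800.0,
    slope=5000.0,
    onset_s=1.0,
    duration_s=2.0,
    fs=1000.0,
    plateau=None,
    trial_type="explosive_1s",
):
    """Flat zero-noise baseline, then a linear ramp starting exactly at onset_s.

    If ``plateau`` is given the ramp stops rising once it reaches
    ``baseline + plateau``.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # build the rise from sample indices so corner and plateau sit exactly
    # on grid points regardless of float time rounding
    onset_idx = int(round(onset_s * fs))
    f = baseline + slope * np.maximum(np.arange(n) - onset_idx, 0) / fs
    if plateau is not None:
        f = np.minimum(f, baseline + plateau)
    return ForceTimeTrial(
        time_s=t,
        force_n=f,
        fs_hz=fs,
        trial_type=trial_type,
        baseline_window_s=(0.0, onset_s - 0.05),
    )


@pytest.fixture
def ramp_trial():
    return make_ramp_trial(plateau=2000.0)


@pytest.fixture
def noiseless_imtp():
    gt = IMTPGroundTruth(noise_sd=0.0)
    return gt, generate_imtp_trial(gt, seed=0)


@pytest.fixture
def noiseless_session():
    gt = CyclingGroundTruth(torque_noise_sd=0.0)
    return gt, generate_sprint_session(gt, seed=0)
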