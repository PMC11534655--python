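"""Analyze one synthetic IMTP trial and compare against its ground truth.

Generates a 1-s explosive isometric mid-thigh pull with a known net peak
force of 2000 N, onset at t = 1.0 s and 20 N of white measurement noise,
then runs the full metric extraction. The printed errors show how close
the automated onset detector and the raw-signal peak come to the truth.
"""

from pedalpull import IMTPGroundTruth, analyze_imtp_trial, generate_imtp_trial

gt = IMTPGroundTruth(pf_true=2000.0, noise_sd=20.0)
trial = generate_imtp_trial(gt, seed=7)
m = analyze_imtp_trial(trial)

print(f"onset time      {m.onset_time_s:8.3f} s   (truth {gt.onset_true_s:.3f} s)")
print(f"net peak force  {m.peak_force_n:8.1f} N   (truth {gt.pf_true:.1f} N)")
print(f"RFD 0-100 ms    {m.rfd_0_100:8.0f} N/s")
print(f"RFD 0-200 ms    {m.rfd_0_200:8.0f} N/s")
print(f"RFD average     {m.rfd_avg:8.0f} N/s")
print(f"RFD peak (20ms) {m.rfd_peak:8.0f} N/s")
# RFD peak is the fastest 20-ms window anywhere after onset, so it always
# dominates the fixed-band values on a rising curve.
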