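"""Published reference values for the modelled study population.

Group summary statistics from a six-week sprint-cycling plus resistance
training intervention in strength-trained novice cyclists (n = 14),
assessed pre and post with an IMTP protocol, a five-sprint cycling
protocol and 3RM gym testing. These printed group moments serve two
purposes: they are the regression targets for the effect-size machinery
(recomputing % change and Hedge's g from the printed means/SDs must
reproduce the printed columns), and they provide realistic population
parameters for the synthetic cohort and session generators.

Three printed cells are internally inconsistent with their own row's
moments under the group ratio-of-means / two-group pooled-SD conventions
(most likely computed from unrounded participant-level data):

* ``ppo_per_bm`` % change prints 10.5 but the printed means give 10.79;
* ``rpm_peak`` % change prints 4.3 but the printed means give 3.78;
* ``rfd_peak`` g prints 0.35 (CI -0.40 to 1.09) but the printed moments
  give 0.43 (CI -0.32 to 1.18).

``PCT_CONSISTENT`` / ``G_CONSISTENT`` flag these per row.
"""

from __future__ import annotations

import pandas as pd

N_PARTICIPANTS = 14

_ROWS = [
    # protocol, metric, pre_mean, pre_sd, post_mean, post_sd,
    # pct_printed, g_printed, ci_low_printed, ci_high_printed
    ("cycling", "ppo_w", 1071.0, 250.0, 1186.0, 246.0, 10.7, 0.45, -0.30, 1.20),
    ("cycling", "ppo_per_bm", 13.9, 2.3, 15.4, 2.0, 10.5, 0.68, -0.09, 1.44),
    ("cycling", "rpm_peak", 185.0, 15.0, 192.0, 14.0, 4.3, 0.47, -0.28, 1.22),
    ("cycling", "t_peak_nm", 207.1, 37.8, 231.4, 35.1, 11.7, 0.65, -0.11, 1.41),
    ("cycling", "rtd_0_100", 291.2, 111.4, 456.4, 171.9, 56.7, 1.11, 0.31, 1.90),
    ("cycling", "rtd_0_200", 522.9, 176.9, 716.1, 224.7, 36.9, 0.93, 0.15, 1.71),
    ("cycling", "rtd_avg", 507.0, 151.9, 657.5, 186.3, 29.7, 0.86, 0.09, 1.63),
    ("cycling", "rtd_peak", 864.9, 252.0, 1106.2, 296.2, 27.9, 0.85, 0.08, 1.63),
    ("cycling", "t0_nm", 165.2, 25.0, 182.0, 29.2, 10.2, 0.60, -0.16, 1.36),
    ("cycling", "pmax_w", 1066.6, 255.4, 1171.9, 265.7, 9.9, 0.39, -0.36, 1.14),
    ("cycling", "rpmmax_rpm", 232.2, 19.4, 234.1, 19.1, 0.8, 0.10, -0.65, 0.84),
    ("cycling", "rpmopt_rpm", 118.0, 10.0, 119.0, 9.0, 0.8, 0.10, -0.64, 0.84),
    ("imtp", "imtp_pf", 1811.7, 573.6, 2049.8, 608.4, 13.1, 0.39, -0.36, 1.14),
    ("imtp", "rfd_0_100", 3303.4, 1862.0, 4246.6, 1828.5, 28.6, 0.50, -0.26, 1.25),
    ("imtp", "rfd_0_200", 2786.7, 1146.9, 3520.1, 1179.2, 26.3, 0.61, -0.15, 1.37),
    ("imtp", "rfd_avg", 2852.5, 1465.4, 3778.8, 2364.0, 32.5, 0.46, -0.29, 1.21),
    ("imtp", "rfd_peak", 11344.2, 5608.7, 14030.1, 6419.9, 23.7, 0.35, -0.40, 1.09),
    ("3rm", "back_squat_kg", 96.0, 25.0, 108.0, 25.0, 12.5, 0.47, -0.28, 1.22),
    ("3rm", "trap_bar_deadlift_kg", 106.0, 35.0, 119.0, 36.0, 12.3, 0.36, -0.39, 1.10),
]

STUDY_SUMMARY = pd.DataFrame(
    _ROWS,
    columns=[
        "protocol",
        "metric",
        "pre_mean",
        "pre_sd",
        "post_mean",
        "post_sd",
        "pct_change_printed",
        "g_printed",
        "ci_low_printed",
        "ci_high_printed",
    ],
)

#: rows whose printed % change reproduces from the printed means
PCT_CONSISTENT = ~STUDY_SUMMARY["metric"].isin(["ppo_per_bm", "rpm_peak"])

#: rows whose printed g / CI reproduce from the printed moments
G_CONSISTENT = ~STUDY_SUMMARY["metric"].isin(["rfd_peak"])

#: pre-training torque-cadence profile parameters of the study group
PRE_T0_NM = 165.2
PRE_RPMMAX_RPM = 232.2

#: mean body mass of the study group (8 men at 83.9 kg, 6 women at 67.3 kg)
MEAN_BODY_MASS_KG = (8 * 83.9 + 6 * 67.3) / 14.0
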