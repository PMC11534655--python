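# pedalpull

Neuromuscular profiling for sprint cyclists: isometric mid-thigh pull
(IMTP) force-time analysis, sprint-cycling crank torque–cadence and
power–cadence profiling, and pre/post training-response statistics — with
synthetic-data generators that carry known ground truth for every stage.

The package is aimed at sport scientists and biomechanists who collect
force-plate IMTP trials and crank-torque sprint data (as delimited text
exports) and want a reproducible, scriptable alternative to spreadsheet
processing: automated force-onset detection, the standard RFD/RTD metric
family, profile fits with extrapolated intercepts, and standardized
effect-size reporting for training interventions.

## What it computes

**IMTP force-time metrics** (no filtering anywhere — all detectors run on
the raw signal):

- Force onset: first sustained crossing of `baseline mean + k·SD`
  (default k = 3, sustained 10 ms), backtracked to the last peak/trough of
  the raw signal before the deflection.
- Net peak force `PF = max F − baseline mean` (the baseline embodies body
  weight on the plate).
- `RFD_0–100` and `RFD_0–200`: `ΔF/Δt` over fixed bands from onset.
- `RFD_avg = (F_peak − F_onset)/(t_peak − t_onset)`.
- `RFD_peak`: the fastest 20-ms window anywhere after onset, by
  exhaustive scan.
- Best-trial aggregation: mean of the best 3 trials per set (5-s sets
  ranked by PF, 1-s explosive sets by RFD_peak).

**Sprint-cycling crank metrics** from five 5-s sprints (stationary starts
at 0.2/0.4/0.6 Nm·kg⁻¹, rolling starts at 0.0/0.2 Nm·kg⁻¹):

- Downstroke segmentation of the 256-Hz crank-torque trace into torque
  lobes; RTD metrics on downstrokes 2–3 of the 0.6 Nm·kg⁻¹ stationary
  sprint, reusing the IMTP machinery with torque substituting force.
- Observed session peaks: PPO, PPO:BM, RPM_peak, T_peak.
- Torque–cadence line `T(c) = T0 (1 − c/RPM_max)` fitted by OLS; `T0` and
  `RPM_max` are its extrapolated y- and x-intercepts.
- Power–cadence cubic `P(c) = a₁c + a₂c² + a₃c³` with the y-intercept
  pinned at zero; its interior apex gives `P_max` and `RPM_opt`.

**Training-response statistics**:

- Percent change (group ratio-of-means, or mean of per-participant ratios).
- Bias-corrected Hedge's g for pre vs post as two groups of size n:
  `g = J · (m₂ − m₁)/s_p`, `J = 1 − 3/(4(2n−2) − 1)`, with the
  normal-approximation 95% CI from `SE² = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))`,
  and the trivial/small/moderate/large/very large/extremely large scale.
- Pearson correlations with two-tailed p on the Hopkins-modified Cohen
  scale, including change-score (Δ vs Δ) correlation matrices.

## Worked example

A noiseless synthetic session generated from the torque–cadence truth
`T0 = 165.2 Nm`, `RPM_max = 232.2 rpm` (the pre-training group profile of
the study population the generators model):

```text
$ python examples/02_sprint_profile.py
T0        165.2 Nm   (truth 165.2)
RPMmax    232.2 rpm  (truth 232.2)
RPMopt    116.1 rpm  (closed form 116.1)
Pmax     1004.2 W    (closed form 1004.2)
observed peaks: PPO 1004 W, cadence 182 rpm, torque 187 Nm
RTD (downstrokes 2-3 of the 0.6 Nm/kg sprint): avg 1221, peak 1847 Nm/s
fit quality: T-C r2 1.0000, P-C r2 1.0000, 20 stroke data points
```

Because the torque–cadence truth is linear, power versus cadence is an
exact parabola and the fitted cubic's apex must land at `RPM_max/2` with
`P_max = π·T0·RPM_max/120` — which it does.

Effect sizes recomputed from the packaged published group moments
(n = 14):

```text
$ python examples/03_training_response.py
    ppo_w:  1071.0 ->  1186.0  Δ +10.7%  g  0.45 (-0.30 to +1.20)  small
rtd_0_100:   291.2 ->   456.4  Δ +56.7%  g  1.11 (+0.31 to +1.90)  moderate
  imtp_pf:  1811.7 ->  2049.8  Δ +13.1%  g  0.39 (-0.36 to +1.14)  small
...
```

The other examples analyze a single noisy IMTP trial against its ground
truth (`examples/01_imtp_trial.py`) and run the full simulate → analyze →
stats pipeline on a 14-participant cohort (`examples/04_full_pipeline.py`).

A thin CLI wraps the same stages:

```sh
pedalpull simulate --n 14 --seed 1 --out-dir study/
pedalpull run --manifest-dir study/ --out-dir results/
pedalpull report --summary results/summary.csv
```

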