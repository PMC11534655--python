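# Methods

This note documents the models, numerical choices and design decisions
behind `pedalpull`, and what the synthetic-data generators do and do not
emulate.

## IMTP force-time analysis

An IMTP trial is a uniformly sampled vertical-force record containing a
quiet-standing baseline window followed by a maximal pull. Two trial types
are handled: short explosive pulls (~1 s, the source of the RFD family)
and sustained maximal pulls (~5 s, the source of net peak force). No
filtering or smoothing is applied at any stage; every detector operates on
the raw signal, so the analysis chain must tolerate raw measurement noise.

**Onset detection.** The field's verbal rule — the last peak/trough before
the signal deflects away from baseline noise — is operationalised as:

1. compute the baseline mean μ and SD σ over the declared quiet-standing
   window (≥ 100 samples for force-plate records; relaxed for crank-torque
   segments, see below);
2. find the first sample exceeding μ + k·σ (default k = 3) that stays
   above the threshold for ≥ 10 ms;
3. backtrack from that crossing to the last strict local extremum of the
   raw signal within a 50-ms lookback; if the preceding signal is flat
   (noise-free), walk down the monotone rise to its corner instead.

In white noise, strict local extrema occur every few samples, so the
detected onset sits within a few milliseconds of the crossing; on
noise-free ramps the corner itself is returned. If the detected rise
overlaps the declared baseline window, the window is shrunk to end 50 ms
before the crossing (with a warning) and the detection repeated once.
k and the lookback are configurable (`RunConfig.k_sd`,
`extremum_lookback_s`).

**Metrics.** Net PF is `max(F) − μ_baseline`; the baseline mean embodies
body weight plus posture load in newtons, which is how "minus the
participant's body mass" is interpreted here (N − N keeps units coherent;
a mass·g subtraction can be substituted by supplying the corresponding
baseline). Tied maxima resolve to the earliest sample. Band RFD snaps the
band endpoint to the nearest grid sample and divides by the nominal band
duration; peak RFD is the maximum of `ΔF/0.020` over every 20-ms window
advanced one sample at a time from onset — an exhaustive scan, asserted
in tests to match an independent brute-force oracle exactly. Best-trial
aggregation takes the arithmetic mean of each metric over the top-3 trials
of a set, ranking 5-s sets by PF and 1-s sets by peak RFD (the published
"best trials" definition lives in an external source; this ranking is the
package's documented stand-in, configurable via `n_best`).

## Crank-torque analysis

Total crank torque (left + right channels summed on read) at 256 Hz is
segmented into downstroke lobes: contiguous runs above 10% of the trace
maximum, extended outward to the adjacent troughs. The trough samples
bounding a lobe belong to top/bottom dead centre and are excluded from the
lobe's mean. RTD on a downstroke reuses the IMTP machinery verbatim with
torque substituting force; the baseline is the 30-ms trough window
preceding the rise (≈ 8 samples at 256 Hz, hence the relaxed
minimum-baseline-sample rule, exposed as `min_baseline_samples`). Whether
torque onset should use absolute zero or the local trough is not settled
in the field; the local trough is the default here. A fixed-band RTD is
computed whenever the record extends a full band past onset, even when the
lobe peak falls inside the band (the band is defined as a quotient of
changes over the fixed window); it is NaN only when the record is
genuinely too short. RTD is reported as the average of downstrokes 2 and 3
of the 0.6 Nm·kg⁻¹ stationary sprint — the strokes where torque is
near-maximal and the rise slow enough to resolve at 256 Hz.

Observed peak power and cadence are maxima over the per-stroke records of
all five sprints. Peak torque is taken from the continuous traces when
they are available (a lobe's instantaneous crest sits ≈ π/2 above its
mean, which is why observed peak torque can exceed the extrapolated T0),
falling back to the largest per-stroke mean torque otherwise.

**Profile fits.** The torque–cadence relation is fitted by ordinary least
squares as `T(c) = b₀ + b₁c`; T0 = b₀ and RPM_max = −b₀/b₁ are
extrapolated intercepts and may legitimately exceed any observed value. A
non-negative slope or non-finite intercept is an error. The power–cadence
relation is the zero-intercept cubic `P(c) = a₁c + a₂c² + a₃c³` (P(0) = 0
holds exactly by construction); it is fitted by least squares on a
cadence-normalised design matrix for conditioning. The apex is the real
stationary point of the cubic inside `(0, 1.2 × max observed cadence)`
with the greatest fitted power (when the cubic coefficient degenerates to
zero the quadratic root is used); absence of an admissible root is an
error, not a silent extrapolation. Only acceleration-phase strokes — each
sprint's strokes up to and including its cadence maximum — enter the
fits, to avoid fatigue-phase contamination.

## Training-response statistics

Hedge's g treats the pre and post samples as two groups of equal size n
with pooled SD `s_p = sqrt(((n−1)s₁² + (n−1)s₂²)/(2n−2))`, bias
correction `J = 1 − 3/(4(2n−2) − 1)`, and the normal-approximation CI
from `SE² = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))`. A repeated-measures d is
deliberately not used: the two-group convention is the one under which
published summary tables of this kind reproduce exactly from their printed
moments, which the test suite asserts row by row at n = 14. Magnitude
bins are half-open with the lower edge inclusive ([0, 0.2) trivial,
[0.2, 0.6) small, [0.6, 1.2) moderate, [1.2, 2.0) large, [2.0, 4.0) very
large, ≥ 4 extremely large), making labels deterministic and monotone;
the same convention applies to the Hopkins correlation scale. Percent
change defaults to the group ratio of means, 100·(m₂−m₁)/m₁; the
mean-of-per-participant-ratios convention is available because published
tables mix the two (see `pedalpull.reference` for the three cells of the
packaged reference table that are only consistent with per-participant
computation — including one effect-size cell whose printed value cannot
be derived from its own printed moments under any pooled-SD convention).
Pearson p-values are two-tailed from the t transform with n−2 df; no
multiple-testing correction is applied. The paired comparison is a paired
t-test on differences — a deliberately simple stand-in for the
mixed-effects modelling a full gender-by-timepoint analysis would use,
which is out of scope here.

## Synthetic data: what it emulates and what it does not

**IMTP trials.** The deterministic curve is a truncated logistic rise
(midpoint 50 ms after onset, steepness 60 s⁻¹ for explosive trials,
30 s⁻¹ for 5-s trials), normalised so the curve attains exactly `pf_true`
above baseline at `peak_time_s`, then decays exponentially (0.3 s⁻¹
explosive, 0.05 s⁻¹ sustained). The post-peak decay reflects how real
pulls crest and fade rather than holding a plateau; it also gives the
curve a unique, identifiable peak, without which the maximum of raw noise
over a long plateau would dominate the PF estimate (the median of the
maximum of white noise over ~10³ plateau samples is ≈ 3.1σ). Truncation
at onset makes the pre-onset record pure baseline noise with a definite
deflection point for onset-recovery testing. Noise is Gaussian and white;
default 1000 Hz sampling (the rate is configurable, band endpoints snap
to whatever grid is supplied). Real force plates add drift, filtering
artefacts and inter-trial posture variation that this generator does not
model — passing recovery tests demonstrates correctness of the metric
definitions under honest noise, not robustness to every instrumentation
pathology.

**Sprint sessions.** Per-stroke cadences approach a condition-dependent
steady state (where the rider's torque line meets the external load)
geometrically: a sprint closes 70% of the gap to steady state, with
successive strokes approaching at ratio 0.45, from 0 rpm (stationary) or
80 rpm (rolling lead-in). Per-stroke mean torques sit on the linear truth
`T(c) = t0(1 − c/rpmmax)` plus Gaussian noise (default SD 5 Nm, which
yields torque–cadence r² ≈ 0.98, matching published fit quality); power
is `T·c·2π/60`. The default of 4 strokes per sprint × 5 sprints gives 20
profile points, matching the ≈ 19.5 points per session reported for this
protocol. The 256-Hz trace realises each stroke as one half-sine lobe
whose sampled mean equals the stroke's torque, separated by zero-torque
troughs occupying 20% of the stroke period. A linear torque–cadence truth
makes the induced power–cadence curve an exact parabola, so the cubic
fit's apex has the closed form `P_max = π·t0·rpmmax/120` at `rpmmax/2` —
the free oracle used throughout the tests. Not modelled: fatigue across
sprints, left/right asymmetry, flywheel inertia dynamics, pedalling-rate
variability within a stroke.

**Cohorts.** Pre values are Gaussian with prescribed mean/SD; post values
apply an additive true change with a configurable pre/post correlation
(default 0.85 — paired training data are strongly correlated). The
confidence-interval coverage test draws the two timepoints independently
(correlation 0), because the g-CI machinery under test models pre and
post as two independent groups and nominal coverage is only defined under
the formula's own sampling model; with correlated draws the interval is
conservative by construction. Population defaults throughout mirror the
modelled study group (n = 14, PPO 1071 ± 250 W, T0 165.2 ± 25 Nm,
RPM_max 232.2 ± 19.4 rpm, net PF 1811.7 ± 573.6 N, body mass 76.8 kg).

## Problem sizes, determinism and degenerate inputs

The shipped tests and the acceptance script use 50-seed recovery batches,
100-trial window-oracle scans, 1000 null cohorts for CI coverage and
14-participant end-to-end runs; these sizes put the Monte-Carlo error of
every asserted median or rate well inside its tolerance while keeping the
whole suite in the tens of seconds. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers (derived via
`SeedSequence` where one seed fans out), so every output — including the
full pipeline bundle — is bit-reproducible. Degenerate inputs fail loudly
with named-field errors rather than propagating NaNs: constant signals
(no onset), inverted trials (maximum inside the baseline), rising
torque–cadence profiles, power curves without an interior apex,
zero-variance vectors, and zero baselines for percent change. The one
deliberate NaN channel is metric "missing-ness": RTD fields when a
session lacks the 0.6 Nm·kg⁻¹ sprint (warned), and band metrics on
records too short for the band.

## Known limitations

- Onset automation approximates a manual-identification rule; on signals
  with structured (non-white) baseline interference the backtracking
  heuristic may land on an interference extremum.
- The best-trial ranking and the downstroke-boundary rule are documented
  stand-ins for definitions that live in external protocol papers; both
  are configurable.
- The paired t stand-in ignores gender effects and participant random
  slopes; with n = 14 and a balanced design its p-values are close to,
  but not identical to, a mixed-model contrast.
- Correlation analyses at n = 14 have wide sampling error; the package
  reports r, p and n but deliberately no post-hoc power claims.
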