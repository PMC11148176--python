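# Methods

`cealab` re-implements, as a tested pipeline, the analysis of a
computerized eye-tracking assessment (CEA) battery used to separate
healthy controls from recent mild traumatic brain injury (mTBI) and
persistent post-concussion syndrome (PPCS).  Because the clinical
recordings are not publicly available, the package pairs the analysis
code with a synthetic-cohort generator whose group presets encode the
published cohort statistics; every extractor is validated by parameter
recovery against the generator's known latents.

## Signal model and preprocessing

Gaze is a single cyclopean point sampled at 133 Hz in screen pixels with
a per-sample eye-to-screen distance; head pose is sampled at 33 Hz.
Pixels are converted to screen-centered degrees of visual angle with
`atan(offset_mm / distance_mm)` using the *per-sample* distance, so
angular extent tracks viewing distance (nominal 700 mm when the distance
channel is absent).  The vertical axis points upward: a positive
vertical fixation error means gaze above the target.

Preprocessing follows the battery's protocol constants, all held in
`cealab.config`:

| rule | value |
| --- | --- |
| trial exclusion by distance | any valid sample < 500 mm or > 950 mm |
| blink handling | any invalid-sample run removed; the gap is recorded and never interpolated |
| velocity | two-point central difference, **no** low-pass filter (filtering at 133 Hz blunts saccadic peaks more than sampling does) |
| saccade detection | maximal run of samples with speed strictly > 100 deg/s spanning >= 50 ms; runs never merge across blink gaps |
| anticipatory screening | response latency strictly < 60 ms removes the trial; exactly 60 ms is retained |

Boundary inclusivity (>= 50 ms, > 100 deg/s, < 60 ms) is fixed as above
for determinism.

## The six tests and their outcomes

* **Fixation stability** (3 x 10 s): 95% bivariate contour ellipse area
  `BCEA = 2 k pi sigma_h sigma_v sqrt(1 - rho^2)` with
  `k = -ln(0.05) ~ 2.9957`, sigmas in minutes of arc, reported as log10
  minarc^2 (floored at 1 minarc^2 for degenerate clouds), plus the mean
  gaze-error vector.
* **Smooth pursuit** (4 x 30 s): the target follows a closed 2:3
  Lissajous figure, `x = 5.5 sin(2wt)`, `y = 3.25 sin(3wt + pi/2)`,
  spanning 11 x 6.5 deg with `w` calibrated numerically so the
  time-averaged path speed is 10 deg/s (sinusoidal motion cannot hold a
  constant speed, so the printed speed is read as the mean; any
  frequency ratio consistent with the printed amplitudes is admissible
  and the 2:3 choice is a config default).  Outcomes: offset error =
  magnitude of the time-averaged (gaze - target) vector over
  saccade-free samples; per-axis gain = least-squares slope of eye on
  target position; total gain = mean of the two axes (the source never
  defines it); catch-up saccade count from the standard detector.
  Saccade windows are masked with a 300 ms pre-pad because a catch-up
  saccade corrects accumulated lag — the pre-saccadic error transient is
  not steady-state offset.
* **Pro/anti saccades** (14 + 14 interleaved): latency from
  secondary-target onset (the open question of which cue starts the
  clock is resolved to the secondary target) to the first detected
  saccade; correctness by the sign of the response's horizontal
  direction versus the target side; response peak velocity.
* **Gaze Stroop** (15 + 15): decision latency = word onset to first exit
  from a 3-deg central region; total time = word onset to the first
  sustained (>= 200 ms) dwell in any 20% x 20% corner block; correct if
  the *final* dwelled corner matches the required color, so corrected
  paths still score.  ROI sizes and the dwell threshold are config
  defaults (unstated in the source).
* **VOR** (10 left + 10 right, alternating): the analysis window runs
  from head-movement onset to 15 deg of cumulative yaw.  Head yaw
  (33 Hz) is linearly interpolated onto the gaze clock.  Instantaneous
  gain = |eye-in-head velocity| / |head yaw velocity|, excluding samples
  with head speed < 20 deg/s; the trial gain is the median ratio.
  Windowed log10 BCEA (saccade-masked), saccade count in the window, and
  time to maximum gain complete the outcomes.
* **Egocentric localisation** (10 trials): targets uniform in the padded
  screen region (15% margins top/left/right, 30% bottom); completion =
  head projection stays within 1.5 deg of its final position for
  >= 500 ms; outcomes are the angular offset of the settled position
  from the target (degrees chosen over millimetres) and the settling
  time.  Note the settling time reads slightly below the underlying
  movement duration because the head enters the settling radius before
  the movement fully ends.

Per-participant outcome values are means over retained trials; the
FeatureTable has one row per participant (x session) and 25 outcome
columns in a fixed, documented order.

## Synthetic cohort generator

Defaults mirror the study conditions: 55 controls, 20 mTBI, 40 PPCS;
the full battery per participant; fixed-seed bit-reproducibility
(`SeedSequence` spawning one stream per participant x test x session, so
simulating a subset of tests reproduces the same traces).

Group presets (`cealab/presets/*.json`) carry the published group
means/SDs where printed — fixation vertical error (-0.29 / -0.38 /
+0.32 deg), pursuit offset error (0.003 / 0.30 / 0.15 deg), vertical
pursuit gain (1.03 / 1.04 / 1.02), catch-up saccades per trial (0.50 /
0.38 / 1.05), VOR stability (3.26 / 3.94 / 3.98 log10 minarc^2).  Two
preset decisions deserve note:

* The mTBI VOR-stability SD is printed as 0.01 alongside 0.94 and 0.90
  for the other groups; this is treated as a typo and the preset uses
  0.90 (the printed value remains available by editing the JSON).
* Pursuit offset magnitude is drawn from a moment-matched gamma
  distribution (nonnegative, mean and SD equal to the printed values)
  with a 5-deg clip.  A folded normal cannot reproduce the printed PPCS
  pair (mean 0.15, SD 0.34), whereas a nonnegative draw with those
  moments makes the recovery targets well-posed.  The control pair
  (0.003 +- 0.26) forces an extreme-skew gamma; occasional large control
  draws are a visible artefact of those printed moments.

Values the source does not print are fixed, field-plausible defaults:
VOR gain means 0.98/0.94/0.95 (SD 0.02-0.04), pro-saccade latencies
0.25/0.29/0.28 s, anti-saccade +0.03 s, correct-rates 0.97-0.92 (pro)
and 0.85-0.76 (anti), Stroop latencies 0.45-0.55 s with correct rates
0.85/0.78/0.75 (part one) and 0.80/0.72/0.70 (part two), egocentric
offsets 1.0-1.6 deg and times 1.5-1.9 s, fixation jitter 0.25-0.30 deg,
and horizontal pursuit gain equal to the vertical preset.  They were
chosen once and are not tuned.

Noise is temporally correlated Gaussian jitter (white noise convolved
with a short Gaussian kernel, rescaled to an exact marginal SD), so
spatial dispersion is realistic while sample-to-sample velocity stays
far below the 100 deg/s detection threshold.  For the short VOR window
the scatter is additionally de-shrunk by the expected small-sample
variance deficit of correlated noise, so the windowed sample BCEA is an
unbiased read-out of the injected stability latent.  Blinks are Poisson
(0.1/s, 100-250 ms) in fixation and pursuit, kept clear of injected
saccades.

**Saccade waveforms.** The run-based detector imposes a hard physical
bound: a saccade can only be detected if it displaces > 5 deg *within*
the suprathreshold run (100 deg/s x 50 ms).  A minimum-jerk velocity
bump can only sustain that run at ~20 deg amplitudes, so injected
saccades instead use a plateau profile — raised-cosine ramps of 10 ms
around a 70 ms plateau, peak velocity `A / 0.08 s`, default amplitude
11.2 deg (peak 140 deg/s, > 100 deg/s for ~77 ms).  This makes every
injected event recoverable (detector recall and precision >= 0.95 in the
test suite) at the cost of amplitudes larger than typical physiological
catch-up saccades; this is a deliberate property of the synthetic data,
not a claim about real eye movements.  Catch-up events are a 250 ms
sub-threshold lag ramp against the direction of target motion followed
by a corrective saccade back to the pursuit path; VOR intrusions are
out-and-back pairs (two detected saccades per event) so gaze returns to
the target and the stability window stays interpretable.

## Statistics

* **Reliability**: two-way mixed, single-measures, consistency ICC —
  ICC(3,1), `(MS_B - MS_E) / (MS_B + (k-1) MS_E)` — with 95% CI from the
  F distribution (cross-checked against pingouin's ICC(C,1)); the
  average-measures variant is available by flag.  Bands: > 0.90
  excellent, 0.75-0.90 good, 0.50-0.75 moderate, < 0.50 poor, with exact
  thresholds assigned to the lower band ("excellent" requires strictly
  greater than 0.90).  Bland-Altman: mean session difference +- 1.96 SD.
  Retest data come from the simulator's paired-session mode (shared
  participant latents, fresh trial noise).  Outcomes dominated by
  trial-level binomial/count noise (correct-rates over 14-15 trials,
  saccade counts) show low synthetic retest reliability by construction.
* **Group comparison**: tie-corrected Kruskal-Wallis per outcome, Holm
  adjustment across the outcome family tested in the run, Dunn's
  pairwise z-tests on pooled ranks (Holm within outcome) as post-hoc —
  the post-hoc procedure is a documented choice, as the source reports
  pairwise p-values without naming one.
* **Classification**: stratified 70/30 split; per-column center/scale
  fitted on the training partition only; group-mean imputation on
  training rows and training-column means on test rows; XGBoost with
  DART dropout, a small fixed grid (depth 2-3, drop rate 0/0.2, 60
  trees, learning rate 0.3) searched by 10-fold stratified CV maximizing
  Cohen's kappa ("10 x cross-validation" is read as 10-fold; fold count
  shrinks below 10 only if a class has fewer members than folds); the
  whole loop repeats over 10 seeds.  Pairwise AUC is the Hand-Till
  one-vs-one mean (cross-checked against scikit-learn's `ovo`).  The
  published clinical performance (kappa 0.75, AUC 0.82) depends on the
  unavailable clinical data; on the cleaner synthetic cohort the same
  protocol scores higher, and the suite instead checks calibration —
  kappa ~ 0 under label permutation, >= 0.95 CV kappa on separable
  fixtures.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — group-mean offsets, gains, latencies, dispersion, event rates,
sampling rates, blink gaps — not the physiology of real oculomotor
behaviour (no main-sequence kinematics at small amplitudes, no pursuit
phase lag, no vergence or pupil signals, no age/gender structure, no
overdispersed saccade counts: catch-up counts are Poisson per group,
which matches the printed means but understates the printed SDs).
Passing recovery tests therefore validates the extraction and
statistics code, and says nothing new about real patients.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 200 participants per group
for cohort means (standard error ~ SD/14) and 35 subjects x 2 sessions
x 20 replicates for the ICC estimator; the full default battery (115
participants, 10,925 trials) simulates and extracts in well under a
minute.  Degenerate inputs are handled explicitly: BCEA floors at
1 minarc^2 for collinear clouds; the ICC is refused when between-subject
variance is zero and returns exactly 1 for bit-identical sessions;
Kruskal-Wallis returns H = 0, p = 1 for all-tied data; empty groups are
skipped in post-hoc pairs; missing responses count as incorrect but
contribute no latency.
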