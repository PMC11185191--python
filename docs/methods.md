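# Methods

This note documents the models, algorithms, and design choices behind
`arcwalk`, in the order data flows through the package.

## Problem setting

Aged-residential-care (ARC) residents walk little, slowly, and mostly in
very short bouts. Characterizing their walking from a week of lower-back
tri-axial accelerometry (100 Hz, ±8 g) requires a processing chain that is
sensitive to low activity volumes: permissive walking thresholds, a low
minimum-bout criterion (3 steps), and macro-outcomes that summarize the
*distribution* of walking, not just its amount. The package implements that
chain and the group-comparison statistics used to contrast care levels,
cognitive status (MoCA), and physical function (SPPB).

## Signal ingestion and orientation

Recordings are long-format delimited text (`time,x,y,z`, seconds or
ISO-8601). After linear-interpolation resampling to a uniform grid
(sampling gaps > 1 s are marked non-wear, never interpolated), the signal
is rotated to a horizontal–vertical frame. Gravity direction is tracked by
a 2nd-order zero-phase Butterworth low-pass at 0.25 Hz — effectively a
~10 s sliding estimate that follows posture but averages out steps — and
the vertical channel is defined as v = −a·ĝ so an upright static wearer
reads −1 g. Horizontal components span the orthogonal complement of the
mean gravity direction, with per-sample rescaling so vector magnitude is
preserved exactly. The output is invariant to any fixed mounting rotation
of the device (verified to < 1e−6 g).

Non-wear is any sampling gap > 1 s plus any ≥ 30-min window with per-axis
SD < 0.005 g on all three axes (a worn device always shows breathing and
posture micro-movement above that).

## Walking-bout detection

1. **Filter**: 2nd-order zero-phase (two-pass) low-pass Butterworth,
   17 Hz cutoff, per channel.
2. **Classify** (1-s sliding windows): *upright* iff windowed mean v ∈
   [−1.15, −0.85] g; *candidate locomotion* iff upright **and** windowed SD
   of vector magnitude > 0.025 g. Posture gating is what excludes lying and
   sitting: in those positions gravity leaves the vertical axis. The two
   numeric thresholds are package choices (no published values exist for
   this population) and are config keys.
3. **Assemble**: candidate runs separated by < 2.5 s are merged (a gap of
   exactly 2.5 s counts as rest and splits); merged episodes with fewer
   than 3 detected steps are discarded. Run edges are eroded by half the
   classification window before the gap comparison, because a sliding
   window smears each true activity edge outward by ~window/2 — without the
   erosion, true rest gaps just above 2.5 s would be merged. Final bout
   edges are snapped to first/last detected step ± half a step period.

A brute-force interval-merging oracle (iterate-to-fixed-point) is kept in
the test suite and must agree exactly with the streaming implementation.

## Step detection

Within each candidate episode the vertical channel is low-pass filtered
(4th-order Butterworth, 20 Hz), linearly detrended, integrated
(cumulative trapezoid — detrending prevents drift), then
smoothed-differentiated by a continuous wavelet transform with a
first-derivative-of-Gaussian kernel; with our sign convention the result
is the Gaussian-smoothed vertical acceleration. Local minima of this first
transform are initial contacts (foot strike); differentiating again with
the same kernel and taking local maxima gives final contacts. The wavelet
scale is cadence-adaptive: scale = 0.4 / f_dom seconds, with f_dom the
periodogram peak in the 0.5–3 Hz locomotor band (fallback to the band
center on flat segments). Extrema must have prominence ≥ 20 % of the
segment's median absolute transform amplitude; initial contacts closing an
interval shorter than 0.25 s are pruned weakest-first, and the plausible
step-time band is [0.25, 2.5] s. Steps per bout = initial contacts inside
the half-open bout interval.

On simulated bouts (cadence 1.4–2.0 Hz) the detector recovers every step
with ≤ 0.02 s timing error noiseless and ≥ 90 % of contacts within 0.15 s
at 0.05 g noise; step-count MAE over 100 mixed bouts is 0 %.

## Macro-outcomes

Per participant, over *valid days* only (calendar days with ≥ 20 h wear;
participants with < 2 valid days are excluded — both thresholds config
keys, the 2-day minimum being the published reliability floor for volume
outcomes):

* **Volume** — walking min/day, steps/day, bouts/day (totals ÷ valid days).
* **Pattern** — mean bout duration; **alpha**, the continuous
  maximum-likelihood power-law exponent of bout durations scaled to the
  participant's shortest bout: α̂ = 1 + N/Σln(xᵢ/x_min). Alpha is undefined
  (NaN) when all bouts are identical. For validation against the truncated
  sampler the estimator also offers the truncated-support MLE (likelihood
  equation solved by Brent's method): the closed form is biased upward by
  ~+0.08 when durations are capped at 600 s, so truncation must be modeled
  when the cap is known. A log-log survival regression is available for
  sensitivity analysis.
* **Variability (S2)** — the lognormal-MLE SD of log bout duration
  (1/N normalization). This reading of the "maximum-likelihood variability
  of bout length" reproduces the published value range (≈ 0.80–0.89) and is
  scale-invariant, but the original formula is not printed anywhere we
  could check against; it is flagged as an interpretation.
* **Bin distribution** — % of bouts in < 10 s, [10, 30) s, [30, 60] s and
  > 60 s. The published bin labels overlap at 10/30/60; we fix half-open
  bins with the 30–60 upper edge closed and > 60 strict, configurable.

## Group statistics

Linear model `outcome ~ group + age + sex`; the group factor is tested by
a partial F test against the covariate-only model (with no covariates this
is exactly one-way ANOVA, agreeing with `scipy.stats.f_oneway` to 1e−10).
Pairwise comparisons use Tukey–Kramer HSD on adjusted (least-squares)
means via the studentized-range distribution with the model's residual df.
Effect sizes are Hedges g from *raw* group summaries — the published
abstract values are recoverable from the printed group means/SDs, which
pins down that convention — with J = 1 − 3/(4·df − 1), df = n₁+n₂−2 (the
1 − 3/(4N − 9) variant is a config option; they differ in the 4th
decimal). Empirical type-I error of the group test is 0.047–0.056 over
1,000-rep null simulations; Tukey family-wise error ≤ 6 %.

Sensitivity analysis removes outcome values outside Q1 − 1.5·IQR /
Q3 + 1.5·IQR fences computed on the pooled analysis sample (type-7
quartiles), then reruns the model and reports the removed count. Pooled
(not per-group) fences are a package choice, configurable.

MoCA maps to intact (≥ 26) / mild (18–25) / moderate (10–17) / severe
(< 10); intact participants are excluded from severity comparisons (small
n). SPPB ≥ 7 is high-moderate, < 7 low-very-low. Missing scores make a
participant "untested" for that grouping only.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated.

* **Bout durations**: truncated continuous power law p(x) ∝ x^(−α) on
  [bout_min, bout_max], sampled by inverse CDF (KS distance to the closed
  form < 0.02 at n = 10,000).
* **Schedule**: per day, a 14-h active window alternates rest gaps
  (shifted exponential with a hard 2.5 s floor, so simulated bouts are
  never mergeable under the rest rule) and bouts. Durations are quantized
  to whole steps: n = max(3, round(d·cadence)), enforcing the 3-step rule
  by construction; steps sit at centers of consecutive step periods.
* **Signal**: device axes aligned with the body frame; az carries −1 g
  plus, per step, a Gaussian-smoothed impulse of width 0.25/cadence s —
  a downward spike at the contact flanked by two half-amplitude rebounds.
  The symmetric zero-mean shape keeps the windowed vertical mean at −1 g
  during walking and leaves the contact-time minimum unmoved under
  smoothing at any scale. White Gaussian noise (default SD 0.01 g) on all
  axes.
* **Care-level profiles** are calibrated to the published group means:
  cadence 1.2–1.3 steps/s (implied by published steps/day ÷ walk-time/day
  for this frail population, below the 1.5–2 steps/s of healthy gait),
  bout caps 90–150 s, rest means 95–190 s, α per group 1.61–1.68. The
  rest-home profile yields ≈ 5.2k steps/day and the dementia profile
  ≈ 135–140 walking min/day, within a few percent of the published 5216
  and 137.
* **Cohort outcome tables** (for testing the statistics layer directly)
  are drawn from zero-truncated normals whose underlying parameters are
  moment-matched so the truncated draws have the requested group
  means/SDs; ages ~ N(84, 7) clipped to [65, 105], ~61 % female.

What the simulator does **not** emulate: non-walking movement (transfers,
wheelchair propulsion), real waveform morphology (no published raw-signal
examples exist to calibrate against), device drift or miscalibration, and
non-wear beyond flat gravity. Passing label-fidelity tests therefore
demonstrates algorithmic correctness under the stated generative model,
not field accuracy on real recordings.

## Numerical choices and degenerate inputs

* Zero-phase filtering throughout (`filtfilt`), so the amplitude response
  is the squared single-pass Butterworth response and phase is zero.
* Free-fall guard in orientation: samples whose low-pass gravity magnitude
  is < 0.3 g carry the last valid gravity direction forward.
* Alpha: all-identical durations → NaN, flagged; truncated-MLE root search
  is bracketed on α ∈ (1, 50].
* S2 of identical durations is exactly 0 (valid).
* Bin percentages always sum to 100 (property-tested).
* Empty inputs: empty mask → no runs; < 1.5 s segments → no gait events;
  segmentation of an empty mask → no bouts.

## Problem sizes

Signal-level validation uses minutes-long active windows (compressed
schedules) and single simulated bouts of 5–40 steps at 100 Hz; estimator
recovery uses n = 5,000 durations (alpha) and n = 1,000 (S2); null
calibration uses 1,000 replicates; the segmentation oracle runs 1,000
random layouts. The full test suite runs in well under a minute; the
acceptance script in a few seconds.

## Known limitations

* The activity thresholds (upright band, magnitude-SD) are stand-ins for
  unpublished values of the original validated pipeline; results on real
  data will be threshold-sensitive, which is why all of them are config
  keys.
* The S2 definition is an interpretation (see above).
* Alpha is computed per participant and averaged; computing it on pooled
  group bouts would differ for heavy-tailed data.
* The per-participant closed-form alpha ignores the finite maximum bout
  length; on strongly truncated duration distributions it is biased
  upward. Published values were presumably produced the same way, so the
  default matches convention rather than minimizing bias.
* Tukey HSD p-values assume homoscedastic normal residuals; the model
  reports a Shapiro–Wilk residual-normality p as a diagnostic, not a gate.
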