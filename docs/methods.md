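# Methods

This note documents the models, conventions and numerical choices behind
`remstim`, and what the synthetic data do and do not establish.

## Closed-loop stimulation model

The online detector watches one EOG channel band-limited to 0.3–5 Hz
(Chebyshev II, >50 dB outside 0.1/15 Hz). When the absolute filtered
amplitude reaches the detection threshold (tunable, 50–100 µV; default
75 µV, 50 µV in the analysis scripts where saccade amplitudes are known)
while stimulation is enabled, an `em_detected` event is logged at the
crossing and a `click` 100 ms later; detection then pauses for
`refractory_s`. Two printed values exist for that pause (2 s in the
protocol text, 2.5 s in a figure legend); the default is 2.0 s and the
value is a config field. Threshold semantics are
first-sample-at-or-above; with continuous-valued signals ties do not
arise, and `>=` keeps the rule deterministic.

The experimenter who enabled/disabled stimulation is replaced by a
deterministic surrogate: `stim_on` at the start of the
`stable_epochs`-th consecutive REM epoch (default 2), `stim_off` at any
stage change or at an arousal onset inside REM, after which the REM run
count restarts. The human criterion ("two or three EMs and reduced chin
activity") is not machine-precise; the run-length rule is the exposed,
reproducible approximation.

The click stimulus is 50 ms of pink noise (power spectral density ∝ 1/f)
with 5 ms linear onset/offset ramps, identical in both stereo channels,
peak-normalized.

## Filters

All four band-passes are minimum-order Chebyshev type II designs meeting
their printed 3-dB passband edges and stopband attenuations as
single-pass targets, realized in second-order sections (high-order
designs with sub-Hz edges at 500 Hz are numerically unstable as transfer
functions). Zero-phase application runs forward–backward with reflected
edge padding and therefore exceeds the printed attenuation (doubled in
dB); whether the printed figures described one or two passes is not
stated, so the single-pass reading is the design contract. At 500 Hz the
orders come out as 4 (online EOG), 17 (offline EEG), 19 (offline EOG)
and 33 (EMG).

## Evoked analysis

Trials span −2 to +3 s around each click. A candidate is excluded
(first matching reason wins) when the click's 30-s epoch is not REM, when
the trial window comes within 2 s of an annotated arousal/artifact, or
when the window crosses the record edge. Trials with bad channels are
spherical-spline interpolated (Perrin kernel, order m = 4, regularization
1e-5, 50 Legendre terms) unless bad channels reach 25% of the montage, in
which case the trial is rejected.

ERSP uses a 6-cycle complex Morlet wavelet (unit energy; power =
|coefficient|²; the normalization cancels in the baseline ratio) on a
0.25–30 Hz grid in 0.25 Hz steps at full scale. After the transform only
−1 to +2.5 s is kept to drop wavelet edge effects; each trial is then
divided by its mean baseline power (−1…0 s) per channel and frequency and
converted to dB, so the dB of the mean baseline power is exactly 0. At
0.25 Hz a 6-cycle wavelet spans 24 s — far longer than the 5-s trial — so
rows below 1.2 Hz are computed but flagged unreliable.

Averaging dB across trials carries a negative offset (the expected log of
a noisy power ratio), identical in every stationary segment. Post-stimulus
changes are therefore quantified relative to the same band's baseline-
segment mean (`post_stimulus_change_db`); condition contrasts cancel the
offset by construction.

## Cluster statistics

Condition differences on subject-level mean maps use pixelwise two-tailed
Welch t-tests. Pixels with p < 0.05 form clusters by 4-connectivity in
(frequency, time) (2-neighbour in 1-D), with positive and negative t kept
separate; cluster size is counted in pixels (not mass). The null is the
permutation distribution of the maximal suprathreshold cluster size under
within-subject condition swaps, sampled without repetition (default 1600
draws; p = (1 + #{null ≥ observed}) / (1 + n_perm)). When 2ⁿ ≤ n_perm the
test enumerates all sign patterns including the identity and reports
p = #{null ≥ observed} / 2ⁿ, which agrees exactly with a full-enumeration
oracle. Per-electrode cluster power supports both the mean (used in the
cluster definition) and the median variant.

## Behavioural scoring

- PVT: mean RT over trials in the closed interval [100, 500] ms (the
  endpoint convention is not printed; closed was chosen).
- VDT: letter-incorrect trials are removed, then accuracy(SOA) is fitted
  by maximum likelihood as γ + (1 − γ − λ)·Φ((SOA − µ)/σ) with guess rate
  γ fixed at 0.5 (two-alternative orientation judgement) and lapse λ
  constrained to [0, 0.06]; the score is the SOA where the fitted curve
  reaches 80%. Trials are aggregated to per-SOA binomial counts (the
  likelihood is identical and the fit ~50× faster). Fits failing to
  converge or thresholds escaping [min SOA/2, 2·max SOA] are flagged.
- MTT: per-trial log on-path time; trials more than 3.5 SD from the
  pooled group mean log-time are removed in a single pass (group
  statistics, not per subject); the score is the mean retained log-time.
- Overnight gain = 100·(evening − morning)/evening, applied verbatim to
  each task's performance value with no per-task sign flipping; direction
  semantics are left to interpretation downstream.

## Statistical layer

Paired comparisons are gated on the Shapiro–Francia test of the paired
differences at α = 0.05 (level and target vector are this package's
choices): paired t when not rejected, Wilcoxon signed-rank otherwise
(exact for n ≤ 25, zeros dropped). Proportions are logit-transformed
first. The Shapiro–Francia p-value uses the Royston log-transform normal
approximation (5 ≤ n ≤ 5000) and matches R's `nortest::sf.test` to ten
decimals on a fixed vector.

The multivariable gain models (gain = β0 + β1·Condition + β2·StageTime)
use OLS with condition coded CNT = 0, STM = 1, matching the signs of the
reported models; the electrode-wise power-vs-gain fits use Huber's
M-estimator (tuning 1.345, IRLS to 1e-8 or 100 iterations). Scale is
estimated by Huber's proposal 2 rather than the MAD, and coefficient
p-values use a t reference with n − k degrees of freedom: with ~12–19
subjects per electrode fit, MAD-scale normal-approximation p-values are
anti-conservative in the far tail (empirically ~3–7× nominal below
p ≈ 0.002), which would break the Benjamini–Hochberg step that screens
the 21 electrodes; the proposal-2/t combination is calibrated there.
Electrode slope p-values are BH-corrected at q = 0.05; survivors are
pooled by mean power for the summary fit.

Between-condition conventions: time/performance differences are CNT −
STM; power differences are 10·log10(power_STM/power_CNT) dB. The paired-t
power analysis evaluates the exact noncentral-t power (df = N − 1,
noncentrality d·√N) and returns the smallest N reaching the target; for
d = 0.7, α = 0.05, power 0.80 it returns N = 19.

## Synthetic data: what it emulates

The generators define the test conditions:

- Hypnograms allocate 30-s epochs by quota to the requested stage
  fractions (defaults mirror a control night: ~20.8% REM of the record)
  split into shuffled bouts (mean 90 s), so empirical fractions match the
  request up to rounding at any duration. Optional Poisson arousals.
- EOG: biphasic raised-cosine saccades, 0.3 s wide (no waveform is
  documented anywhere; only the 50–100 µV amplitude interval matters to
  the detector), Poisson 6/min restricted to REM epochs, over 5 µV RMS
  pink noise.
- EEG: 1/f background at 30 µV RMS per channel with extra REM theta; per
  click an additive ERP (Gaussian P2 at 275 ms, 6 µV, σ 45 ms — amplitude
  chosen as a realistic auditory P2 in sleep — plus a −3 µV sin²
  negativity over 0.5–1.5 s) and multiplicative band-limited gain
  envelopes implementing the beta increase (+1 dB, 15–25 Hz, 0.2–1.4 s)
  and theta decrease (−1 dB, 4–8 Hz, 0.7–1.5 s); effects are injected by
  scaling the signal's own band content so the dB baseline transform
  recovers them directly, and zero-amplitude ground truth reproduces the
  background exactly.
- Behaviour: subject-level overnight gains drawn around task baselines
  (between-subject SD 10, night residual SD 15 percentage points, chosen
  to match the reported effect-size scale), with condition effects
  (defaults +20.71 VDT, −11.60 MTT, 0 PVT percentage points) entering the
  post-sleep performance parameter multiplicatively; MTT gains are
  truncated to ±60 points because the MTT value is a log-time and larger
  swings would imply implausible e^±2.5-fold time changes. Trial tables
  follow the task protocols (PVT shifted-lognormal RTs; VDT Bernoulli
  draws from the subject's psychometric curve over the 9-level SOA ladder,
  50 trials per level; MTT log-normal times over six figures).

What it does not emulate: realistic spindle/slow-oscillation morphology,
NREM microstructure, volume-conducted channel correlations, ocular/cardiac
artifacts (the pipeline consumes annotations; ICA is an upstream step),
or learning-order effects. Passing tests therefore establish correctness
of the computations and calibration of the statistics under the stated
noise model, not performance on recorded polysomnography.

## Problem sizes used in tests and scripts

Simulation-based checks run at reduced scale, chosen once: synthetic
nights of 30 min at 200–250 Hz with 4–8 channels; ERSP window-recovery
runs use six channels and 160 trials at 250 Hz, sized so the window
estimate's sampling noise is small against the injected 1 dB; the
cluster-detection
experiments use the study's cohort size (19 paired subjects) with 80
trials per condition on one channel at 125 Hz, a 2–30 Hz grid in 1 Hz
steps and a decimated time axis; the
cluster-test calibration uses 200 null experiments of 10 subjects on
smoothed-noise 12×30 maps with 500 permutations (the family-wise error of
the permutation scheme does not depend on the map's provenance); the
full-pipeline null is exercised once in the ERSP null-injection test.
Fixture EDFs are written at 16-bit precision; round-trips are verified
against an independent reader (MNE) to within one quantization step.

## Known limitations

- The online filter's group delay (causal mode) slightly delays threshold
  crossings relative to the raw saccade onset; the reported
  "% clicks on the triggering EM" is sensitive to the saccade-extent
  window used to judge it (default 0.3 s, the generator's saccade width).
- Sub-1.2 Hz ERSP rows are flagged, not removed; users aggregating over
  frequency should respect the flag.
- Huber fits fall back to the MAD scale when the proposal-2 iteration
  degenerates (e.g. exactly collinear data with zero residuals).
- The Wilcoxon exact path requires n ≤ 25 unique non-zero differences;
  beyond that the normal approximation with continuity correction is
  used.
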