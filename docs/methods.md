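# Methods

This note documents the models, parameter choices and numerical
conventions behind the `dmmn` package: what the synthetic generator
emulates, how the analysis operations are defined, and where genuinely
open design choices were resolved.

## Stimulus paradigms

Schedules are specified by session length and SOA; the trial count is
⌊session_length / SOA⌋ (computed with a 1e-9 epsilon so that 165 s at
0.55 s gives exactly 300 trials).  Time zero is the first tone onset;
onsets are stored in seconds at microsecond resolution.

* *Pure tone*: five frequencies (1, 2, 4, 8, 16 kHz), 500-ms tones, 3-s
  SOA, a seeded permutation with an equal count per frequency.
* *Oddball*: 50-ms standards, 100-ms deviants, independent Bernoulli draws
  at probability 0.1 per trial.  No adjacency or warm-up constraint is
  imposed by default — a deviant may occur on the first trial or twice in
  a row; an optional `min_separation` parameter suppresses close deviants
  for users who want the constrained variant.  A 165-s session yields 300
  trials and 30 deviants in expectation.
* *Many-standards*: ten durations (10–225 ms, arithmetic mean 113.5 ms),
  i.i.d. seeded draws with equal probability; the first tone's duration
  can be forced (the first-vs-later adaptation control needs sessions that
  open with a 100-ms tone).
* *Standard blocks*: ten 50-ms tones per block at an SOA of 550 or 350 ms,
  blocks separated by 10 s (measured onset-to-onset), with 1-based
  within-block position labels.
* *Photostimulation overlay*: a seeded 10% of tones (or virtual, silent
  tones) flagged as followed by a 300-ms laser window at tone end — ten
  10-ms pulses with 20-ms gaps (280 ms from first pulse onset to last
  pulse offset).

Identical arguments and seed reproduce a schedule bit-exactly; this is a
hard invariant of the package.

## Synthetic data generator

The generator produces data whose *planted parameters are recoverable by
the downstream analysis*; its defaults were chosen by closed-form design,
not by fitting any real recording.

**Tuning.** Gaussian in log₂ frequency with a width in octaves (default
1.0), normalised to 1 at the best frequency.  Real tuning curves are not
Gaussian and the field summarises them by the selectivity index only; the
Gaussian is the simplest shape with a controllable width.

**Calcium kernel.** Difference of exponentials, rise 0.05 s, decay 0.4 s
(GCaMP6f-like), sampled on the 30-Hz frame grid and normalised to unit
peak, so an impulse of height *d* yields a peak ΔF/F₀ of *d*.  The
constants are configurable and are not claimed as measurements.

**Onset/offset drives and adaptation.** Each tone contributes an onset
impulse (onset_gain × tuning × a) at the onset frame and an offset impulse
at the tone-end frame.  The resource *a* follows depletion
a ← a·(1−u) per presentation and exponential recovery toward 1 with time
constant τ.  Area presets:

| area  | u    | τ (s) | steady-state attenuation at 550 / 350 ms SOA |
|-------|------|-------|----------------------------------------------|
| core  | 0.95 | 0.08  | ~0.1% / ~1.2%                                |
| ML/CL | 0.95 | 0.20  | intermediate                                 |
| RPB   | 0.95 | 2.0   | ~75% at 550 ms, duration-independent         |
| CPB   | 0.95 | 0.30  | intermediate                                 |

The core preset recovers almost fully within 550 ms but measurably less
within 350 ms, giving the qualitative SOA dissociation; the RPB preset
(slow recovery) stays suppressed at a low steady level even at 550 ms.
The LFP noise scale (default 0.0015 of the unit deflection) was set by a
power calculation: the 350-ms attenuation (~1.2% of the 0–200-ms window
amplitude) is ~2.4 SD of a block-position amplitude, so the
signed-rank-over-blocks test detects it at 16 blocks, while the 550-ms
attenuation (~0.1%) sits far below the noise floor.

**Deviance injection.** An amplitude is added to the offset impulse when
the tone's duration deviates from the *modal* duration of the trailing 20
presentations by more than 25 ms **and** that mode accounts for at least
60% of them (at least 10 presentations of history).  The dominance gate
encodes the idea that a prediction error requires an established
regularity: an equiprobable many-standards stream never triggers an
injection, so the planted amplitude is exactly the oddball-vs-control
difference.  The mechanism is phenomenological — the analysis target is
the signal, not its biophysical origin — and the generator's temporal
profile is tuned to qualitative shape only.

**Neuropil mixing.** Recorded ROI fluorescence is
F_roi = F_cell + r_true·F_neuropil + noise, with F_cell =
baseline·(1 + kernel ⊛ drives).  The neuropil trace carries the scaled
population mean response (gain 0.15), a slow sinusoidal drift (amplitude
0.2 of the neuropil baseline, 60-s period) and its own noise.  The drift
provides variance in F_neuropil that is absent from F_cell, which is what
makes the contamination slope identifiable by regression; with the default
settings the residual identification bias is below 0.01.

**One-photon movies.** Each pixel responds according to a planted BF map
(by default five vertical bands along the rostro-caudal axis, low to high
frequency); adaptation state is tracked per area; vignetting is a radial
multiplicative profile and noise has a shot-like intensity-scaled term.
Movies of arbitrary length are generated by chunked convolution with
identical output.

**LFP.** A stereotyped deflection (dominant negative phase peaking at
40 ms, positive rebound at 130 ms; signed 0–200-ms mean ≈ −0.17 of the
unit amplitude) is scaled by amplitude × a per tone, on a 1/f Gaussian
background, sampled at 24 kHz by default.  Recordings start 1 s before
the first tone so every trial has a full pre-onset baseline.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biophysical spiking, optics/PSF, motion
artifacts, non-Gaussian noise, bleaching, cross-neuron correlation
structure beyond the shared neuropil term, and real tuning-curve shapes.
Recovery results certify the correctness of the estimators under the
stated model, not their robustness to every property of real recordings.

## Preprocessing

* **Binning** is block averaging (mean, not sum, so ΔF/F₀ is unchanged by
  binning); non-divisible shapes are edge-padded with a warning.
* **Neuropil correction**: per ROI, timepoints with F_roi above its
  time-mean + 1 SD are excluded (removing evoked transients), then F_roi
  is regressed on F_neuropil by IRLS with bisquare weights (tuning
  constant 4.685, max 50 iterations, tolerance 1e-8, intercept estimated
  and discarded).  ROIs with fewer than 30 usable timepoints, or with
  zero-variance neuropil (slope defined as 0), are flagged; the field
  factor r is the median of the remaining slopes and the corrected trace
  is F_roi − r·F_neuropil.  One-photon pipelines skip this step — it is a
  two-photon ROI correction.
* **ΔF/F₀ and alignment**: tone onsets snap to the nearest acquisition
  frame (error ≤ half a frame period; the 550-ms SOA on a 30-Hz grid
  places onsets on half-integer frames, so the snap alternates direction
  between trials).  F₀ is the mean over the pre-onset baseline window (10
  frames for the pure-tone analysis, 5 frames for the dMMN analysis).
  Trials with truncated windows are dropped with a warning; trials with
  F₀ ≤ 0 (possible after neuropil subtraction) are excluded rather than
  clipped, to avoid sign flips, and counted in the QC record.

## Classification

* **Tone responsiveness** needs (1) three consecutive post-onset frames of
  the trial-averaged trace above 1.96 × the baseline SD and (2) a
  significantly positive per-trial response-window mean (two-sided
  signed rank, P < 0.05).  The SD in criterion (1) is computed on the
  trial-averaged trace over the baseline window — the conventional noise
  floor; a per-trial-pooled SD is available behind the `sd_mode` switch
  since either reading is defensible.  The two-photon gate additionally
  requires the window-mean ΔF/F₀ to exceed 0.01.
* **BF** is the argmax of the 1-s window mean across the five frequencies;
  exact ties break toward the lower frequency (deterministic and
  documented).
* **SI** clips negative baseline-subtracted responses to 0 before scaling,
  which guarantees the range [1, 5].
* **Onset+/offset+**: 15 frames after the onset (end) versus 5 frames
  before it, signed rank at P < 0.05 with a positive mean; both flags give
  the onset+offset+ class.  For tones shorter than 0.5 s the onset window
  contains the tone end; this overlap is inherent and flagged.
* **dMMN responsiveness** tests twenty groups — the deviants, nine seeded
  near-equal random groups of the oddball standards (sizes differ by at
  most 1), and the ten duration groups of the many-standards paradigm —
  each for a significantly positive 0.5-s window mean with a group mean
  above 0.01 ΔF/F₀; groups below 5 trials are skipped and recorded.

## Deviance analysis

* **Control-trial filter**: 100-ms many-standards tones whose immediately
  preceding tone lasted 10, 25 or 50 ms, matching the 50-ms standard that
  precedes a deviant so that the decaying calcium response contaminates
  both baselines comparably.  First trials are never selected.  A
  permissive mode uses all non-first 100-ms tones.
* **Per-timepoint testing**: two-sided rank sum per frame/bin, BH-FDR
  across the timepoints of one aligned window of one comparison (not
  across sessions or regions; the FDR family is the window).  All-tied
  timepoints get p = 1.  Because the directional claim ("significantly
  higher") is made with a two-sided test, the reported mask combines the
  FDR-adjusted two-sided p with a positive-difference gate; the pure
  two-sided mask is also exposed.
* **Window → frame mapping**: a frame belongs to a window when its start
  time lies inside it, both ends inclusive (with 1e-9 ms tolerance); at
  30 Hz the 200–400-ms window is frames 6–12.  A centre-inclusion rule
  was considered and rejected to keep both window ends represented on the
  coarse 33-ms grid.
* **Amplitude estimation**: the template-based estimator divides the
  deviant-minus-control mean over the post-tone-end window by the mean of
  the calcium-kernel template over the same frames, accounting for each
  trial's exact frame-snapped tone-end position.  In recovery analyses the
  deviant set is restricted to trials after the regularity is established
  (index ≥ 10) whose predecessor was a standard — the same
  previous-duration logic as the control filter, applied symmetrically;
  without it, injected responses of clustered deviants decay into the
  next deviant's baseline and bias the estimate low.
* **Deviance maps** gate 16×16-binned segments on deviant-tone
  responsiveness before testing; the half-maximum display floor is a
  rendering transform only — the data values are preserved.
* **Photostimulation comparison** averages over segments responsive to
  tone-plus-stimulation, excluding segments responsive to stimulation
  alone (virtual-tone sessions), and compares 333–500-ms window means
  with a rank-sum test and Cohen's d.
* **Cohen's d**: mean difference over the pooled (n−1)-weighted SD;
  paired mode uses mean/SD of the differences.  Identical samples give 0;
  zero variance with unequal means is flagged as undefined.

## LFP analysis

Non-overlapping 10-ms bins from −100 to +500 ms around each onset (60
bins); each bin is the mean of its raw samples and the per-trial baseline
is the mean over the pre-onset bins (the baseline span is a package
convention — only its subtraction is standard).  Analysis operates on
signed amplitudes (no rectification), consistent with plotting signed
averages; a magnitude option exists where the signed mean would cancel.
The bin-wise deviance test is the same implementation as the calcium
timecourse test, parameterised by the grid.  Adaptation-by-position
compares the first tone of each block with each later position across
blocks (signed rank, BH-FDR over the later positions) on 0–200-ms window
means.  Hardware filtering is treated as a property of the input data.

## Problem sizes

Tests and examples run sessions at the paradigm's native scale (300-trial
oddball and many-standards sessions, ~30 deviant and ~8 filtered control
trials), 16–18 standard blocks per LFP session, 50-ROI fields for
neuropil recovery, 500 replicates for the FDR-null check, and 20 sessions
per planted amplitude for recovery; movies use reduced frame sizes
(16×20 to 32×48 pixels) since pixel count only scales the map statistics,
not the per-pixel computation being verified.

## Known limitations

* The deviance mechanism is injected, not emergent; the package cannot be
  used to study how prediction errors arise, only whether the analysis
  recovers them.
* The amplitude-recovery guarantee (≤10% relative bias) holds for the
  documented session conditions; with large evoked gains the running-F₀
  elevation compresses measured ΔF/F₀ by up to tens of percent — a
  property of the ΔF/F₀ convention itself, visible in the generator.
* FDR control is certified under the global null with independent trials;
  correlated noise across frames shifts the realised false-discovery
  proportion, though BH remains valid under positive regression
  dependence.
* The onset/offset classification windows overlap for tones shorter than
  0.5 s; classifications for such tones describe window contrasts, not
  disjoint response phases.
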