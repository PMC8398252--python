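# Methods

This note records the models, parameter choices and numerical conventions
behind `ecgbeats`, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

A record is a single-lead voltage trace in millivolts at sampling rate
`fs`; the pipeline's reference rate is 360 Hz, and other rates are
polyphase-resampled to it (annotation indices rescaled with
round-half-away-from-zero).  Working at one fixed rate keeps every window
length and filter design constant and bit-reproducible; the alternative —
scaling window lengths to the native rate — would trade that for slightly
less resampling distortion.

The primary denoiser is a four-stage cascade:

1. subtract the mean (DC removal);
2. subtract a running median with window `round(a_median · fs)` forced odd
   (`a_median = 0.9` s → 325 points at 360 Hz).  A 0.9 s median of ECG
   straddles several beats, so it tracks the baseline and is immune to the
   QRS spikes; subtracting it is the first baseline correction.  Edges use
   reflect padding to avoid boundary transients;
3. a linear-phase band-pass FIR, 342 taps, Kaiser window β = 4.538, band
   0.05–40 Hz.  The kernel is symmetric; it is applied in the frequency
   domain with its linear phase removed exactly, so the net group delay is
   zero even though 342 taps imply a half-sample delay in a causal
   implementation.  R-peak timing downstream depends on this.
4. a second identical median subtraction, then removal of the residual
   mean (the median stages are not exactly mean-preserving).

Division of labour: **baseline wander is removed by the median stages, not
by the FIR.**  At 360 Hz a 342-tap FIR has a transition band of a few Hz;
its response at 0.01 Hz is within half a dB of the passband, so the
0.05 Hz lower edge is nominal.  The measured cascade attenuates a 0.01 Hz
sinusoid by more than 20 dB (the median stages do this), while the FIR's
upper edge provides > 20 dB at 50/60 Hz mains — which is also why no
separate notch stage exists.

### EMG suppression

EMG noise overlaps the QRS band, so a linear filter cannot separate them.
The package uses a one-state random-walk Kalman filter: state = clean
voltage, predict `x̂_k = x̂_{k−1}`, `P += q`, update with gain
`K = P/(P+r)`.  Parameters:

* `r` (measurement variance, mV²) — default estimated from the signal as
  `var(diff(x))/2`, an unbiased noise-floor estimate when the noise is
  white and dominates the first difference;
* `q` (process variance, mV²) — default `r/2`, which puts the steady-state
  gain near 0.5: broadband noise power is roughly halved while waves up to
  ~tens of Hz pass with mild attenuation.  A fixed small `q` (say 1e-4) is
  tempting but behaves badly across signal scales: for realistic noise
  levels it collapses the filter bandwidth to ~1 Hz and smears the ECG
  itself, which is why the default adapts to the measured noise floor.
  Both parameters accept explicit values.
* Inside ±60 ms guards around the fiducials (a typical QRS duration) `r`
  is divided by 100, driving the gain toward 1 so the fast QRS deflections
  are tracked, not smoothed.

## R-peak detection

The detector reuses the feature filter pair in à-trous (undecimated) form:
at each level the filters are dilated by inserting zeros, and the
cumulative fractional group delay of the chain is compensated to keep the
detail signals aligned with the input.  A QRS appears at scales 2² and 2³
as a pair of opposite-signed modulus maxima; the zero-crossing between
them marks the R wave, refined to the largest-magnitude signal sample
within ±25 ms (ties go to the larger amplitude, then the earlier index).

Thresholding: candidates must exceed `threshold_factor` (default 4.0)
times a per-2 s-window *robust* background RMS, estimated as
1.4826 · median(|w|) — the Gaussian-consistent MAD scale.  A plain RMS
would include the QRS responses themselves and can mask wide,
lower-slope ventricular beats.  The estimate is floored at 2% of the
global maximum so near-silent windows do not admit numeric ripple;
because both the estimate and the floor are relative, detection is
invariant to positive rescaling of the signal.  An all-zero transform
returns no peaks.

Post-processing: a 200 ms refractory period (physiological minimum RR)
keeps the stronger of two close candidates; RR gaps exceeding 1.66× the
running median RR trigger a search-back over the gap with the threshold
halved, iterated up to three times since a recovered beat splits its gap.

For classification experiments on externally annotated databases the
pipeline defaults to the reference annotation positions as fiducials
(`fiducial_source="annotations"`), which compares classifiers rather than
detector+classifier stacks; `"detector"` switches to detected peaks, and
beats whose detection matches no annotation within 50 ms are dropped from
training/evaluation with a logged count.  Both paths are first-class and
the configuration is echoed into every output directory.

## Features

Fragments are 151 samples with the R sample 51st (0-based index 50).
Eligibility requires 50 samples of history, 100 of future, and both a
previous and next peak (for `RRpre`/`RRpos`); the first and last beats of
a record are therefore never featurized.  Internally all indexing is
0-based half-open; the 1-based closed conventions of the feature
definitions are translated once, at this module's boundary.

* `Ratio_ud` divides the positive-sample sum by the *magnitude* of the
  negative-sample sum, so it is positive for mixed-sign fragments.
* Denominator magnitudes in both area ratios are floored at 1e-6 mV·samples:
  after baseline removal a wearable fragment can be one-sided, and the
  features must stay finite.
* `Dif` is evaluated over fragment positions 21..101 (1-based): an
  81-sample ≈ 225 ms window split 30:50 = 3:5 before/after R — the closest
  sample grid to a 220 ms window with that split at 360 Hz.
* The DWT uses symmetric boundary extension with per-level output length
  `floor((n−1)/2) + 3`, giving 78/41/23/14 from 151 and the 51 retained
  coefficients a4(14) + d4(14) + d3(23).  Boundary handling changes
  coefficient values near fragment edges but not the lengths; symmetric
  extension is the common default and is fixed here for portability.  The
  implementation (PyWavelets with a custom filter bank) is verified
  against an independent direct-convolution oracle to < 1e-10.
* The vector layout `[RRpre, HRVloc, Ratio_lr, Ratio_ud, Dif, a4(14),
  d3(23), d4(14)]` is arbitrary but frozen; a hash of it travels with
  every trained model and is checked at prediction time.

## Classifier

Tree construction is delegated to XGBoost (`multi:softmax`, `merror`,
histogram method, single thread); this package owns the configuration,
label codes, integrity checks and the split-weight importance report.
Defaults are the tuned values: 164 estimators, depth 11, subsample 0.6,
colsample_bytree 48/56, L1 α = 0.01, η = 0.2, min_child_weight 1; γ and λ
stay at engine defaults as no tuned values exist for them.
`scale_pos_weight` is recorded in the config but not passed to the engine:
it is a binary-task parameter, and its recorded value 1 equals the engine
default.  Training with subsample < 1 makes the engine sensitive to row
order in principle; the seed is fixed, and the test suite checks that
predictions on well-separated data are unaffected by shuffling.

Importance is the split-weight convention: how many times each feature
splits a node, normalized to percentages over the 56 features, with group
totals for {morphological, a4, d3, d4}.

## Evaluation

One-vs-rest counts per class give Se, +P and F1 in percent.  The headline
accuracy is overall multiclass accuracy, `100·trace/total` — the
convention comparable across published per-class reports; the per-class
one-vs-rest accuracy `(TP+TN)/total` is also computed and macro-averaged,
since that alternative reading exists (it is systematically higher and
should not be confused with the headline).  A class with no support yields
NaN metrics, is excluded from macro means and is listed in the report's
`undefined` field — never silently coerced to 0 or 100 (rare-class
reporting honesty).  JSON serialization writes NaN as null.

## Synthetic generator

The generator emulates an annotated wearable single-lead recording with
additive Gaussian-wave beat templates (direct, per-parameter control over
exactly the quantities the features measure — QRS width drives
`Dif`/`Ratio_lr`, prematurity drives `RRpre`/`HRVloc`):

* N: P–QRS–T with a narrow (σ = 13 ms) dominant R;
* S: normal QRS, attenuated early P, preceding RR shortened 20–40%;
* V: no P, wide QRS (> 120 ms at 10% amplitude), discordant T, slight
  prematurity with a compensatory pause after;
* F: per-wave average of the N and V templates (fusion morphology);
* Q: 2 ms, 1.5 mV pacing spike 20 ms before a widened low-amplitude QRS.

The RR process is Gaussian (σ = 3% of mean RR, clipped to 0.4–1.8×) with
the class-driven modifications above.  Default conditions: 72 bpm, class
mix 0.90/0.03/0.05/0.01/0.01 (the N-dominated skew of ambulatory data),
0.15 mV baseline wander at 0.25 Hz, 0.05 mV mains at 50 Hz, and EMG —
band-limited (20 Hz–0.45·fs) Gaussian noise — scaled to 20 dB SNR against
the clean trace.  Output is quantized to a 1/200 mV ADC grid, making WFDB
round trips bit-exact.  One seeded generator drives all randomness.

What passing on this benchmark does **not** show: real inter-patient
morphology variability (every synthetic "patient" shares the same
templates), non-stationary noise, electrode motion artifacts, atrial
fibrillation rhythms, or the heavily overlapping class boundaries of real
databases.  Synthetic accuracy near 100% is expected by construction
(the separability invariant); it validates the plumbing and the feature
definitions, not clinical performance.  Conversely, detector sensitivity
and SNR numbers are measured against exact ground truth, which no real
database provides.

## Problem sizes

The test suite and the acceptance script use 60 s records for detector
checks and a ten-record, ~5,000-beat corpus (5 × 7 min train, 5 × 7 min
test) for the end-to-end experiment — large enough for stable class counts
in the 1% classes while keeping a full run in seconds.

## Known limitations

* WFDB support covers format 16 and the MIT annotation codes needed here,
  not the full format family (e.g. formats 212/80, multi-segment records).
* The Kalman stage is a documented one-state stand-in with the intended
  behaviour (EMG suppression with QRS preservation); richer state models
  (slope + level, or ECG dynamical models) would suppress more noise at
  equal distortion.
* The detector is tuned for single-lead morphologies with a dominant R;
  very low-amplitude QRS or flutter waves may require a lower
  `threshold_factor`.
* Beat counts per class on external databases depend on which records are
  excluded (the paced records) — both conventions can be computed with
  `default_split()` and the annotation reader.
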