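# Methods

`seizewear` implements an end-to-end analysis of multichannel wristband
recordings from children with epilepsy: preprocessing, sliding-window
segmentation, a 120-feature window representation, an imbalance-aware
boosted-tree ensemble for seizure-window classification, event-level
evaluation, and cohort-level developmental ("physiome") profiling.  Because
no patient data ship with the package, a synthetic generator produces
cohorts with the statistical structure the analysis assumes; every claim in
the test suite is made against data from that generator or against
closed-form oracles.

## Data model

A subject record holds one stream per sensor channel — heart rate (HR,
1 Hz, bpm), galvanic skin response (GSR, 0.2 Hz, µS), tri-axial
accelerometer (ACC, 8 Hz, g) and gyrometer (GYR, 8 Hz, deg/s) — plus
caregiver-style seizure annotations and wear intervals.  Timestamps are
integer Unix milliseconds; every interval in the package is half-open
`[start, end)`, which avoids double counting at window edges.  Missing
samples are absent rows, never NaN sentinels; the missing fraction of any
interval is `1 − observed/expected` at the nominal rate.

## Preprocessing

Per channel, in order:

1. **Signal-quality identification (SQI).**  Non-wear time is dropped
   outright.  60-s non-overlapping windows with *strictly more than* 60% of
   expected samples missing are dropped; exactly 60% is kept.
2. **Wavelet denoising.**  Multilevel DWT with a Daubechies-6 basis and
   symmetric padding, computed on gap-free runs (runs shorter than
   `2^levels` samples pass through).  Motion channels use 5 levels with the
   fifth detail level (0.125–0.25 Hz at 8 Hz — the standard dyadic band
   closest to the nominal 0.1–0.25 Hz description) zeroed outright, since
   seizure-relevant movement energy lies at 0.25–4 Hz.  The HR channel is
   first converted to a pseudo R-R interval series (RRI = 60000/HR ms at
   the 1-Hz sample clock) and denoised with 4 levels, no zeroed bands.
   Remaining detail levels are hard-thresholded (`|w| ≥ µ` keeps, boundary
   included) at a single global VisuShrink threshold
   µ = σ̂·√(2·ln n), σ̂ = median(|D1|)/0.6745, estimated once from the
   finest detail level of each run.
3. **Trim and smooth.**  Values strictly below the 5th or strictly above
   the 95th percentile of the subject–channel recording are removed
   (marked missing, not clipped); a centered 5-sample moving average then
   smooths the survivors, shrinking at gaps and edges.  The width is
   configurable; 5 samples was chosen as a minimal smoother at the 1-Hz HR
   clock.  Percentiles are computed over the whole recording, not per
   window.
4. **Personal baseline.**  The subject–channel median of retained values
   is subtracted, so every downstream feature describes departure from the
   child's own baseline; the residual median is exactly 0.

ACC/GYR **magnitude** (`√(x²+y²+z²)`) is derived from the *denoised,
pre-trim* axes and then trimmed/smoothed/residualized as a channel in its
own right.  Computing it from per-axis-trimmed samples instead induces a
selection bias (samples pushing outward along an axis are preferentially
removed) that can make in-event magnitude appear *lower* than baseline.

**Pseudo-RRI caveat.**  True beat times are unavailable from this class of
optical wrist sensor, so all HRV quantities are defined on the uniformly
sampled 1-Hz pseudo-RRI.  This preserves rank structure (suppressed
variability stays suppressed) but absolute band powers are not comparable
to ECG-derived HRV, and the 5-sample moving average attenuates the HF band
(0.15–0.4 Hz) strongly; LF/HF at the 60-s window scale is therefore
leakage-dominated and noisy (see Limitations).

## Segmentation and labeling

Three window grids: 60 s / 30 s step for classification, 300 s / 60 s step
(80% overlap) for HRV/motion epochs, 60 s non-overlapping for QC.  Windows
fitting entirely inside the span are emitted; the count is
`floor((T − length)/step) + 1`.

A window overlapping a seizure interval by any amount is **positive**
(containment labeling would starve the positive class: 81.3% of events
last under a minute).  Windows overlapping only the 60-s buffer zones
flanking an event are **buffer-excluded** — dropped from training and from
false-alarm counting, though their time still counts toward monitored
hours.  Windows with more than 60% of any core channel missing, or outside
wear time, are **QC-excluded** (this uses raw sample presence; trimmed
extremes do not count as missing).  Windows whose ACC-magnitude standard
deviation (N−1 denominator, computed on the denoised pre-trim magnitude)
is strictly below 0.1 g are **resting**: resting non-seizure windows are
excluded from training, and every resting window is forced to score 0 at
prediction, rest being treated as a non-motor, non-seizure state.  At the
5-minute epoch scale the same rule is applied per sliding position with a
majority vote; ties resolve to *active* so potentially seizure-bearing
epochs are never discarded on a tie.  Exactly 0.1 g is active (strict
reading of "below").

## Features (120 per 60-s window)

Ten summary statistics — max, min, mean, median, sample SD (N−1), Q1, Q3,
10th and 90th percentiles (linear interpolation), peak difference
(max − min) — for each of HR, RRI, GSR, ACC x/y/z/magnitude and GYR
x/y/z/magnitude (110 features), plus ten HRV parameters on the window's
RRI: SDNN, RMSSD, SDSD, NN50, pNN50 (successive differences; pairs across
missing samples are dropped) and Welch-based VLF (0.001–0.04 Hz), LF
(0.04–0.15), HF (0.15–0.4), LF/HF and total power.  The Welch estimate
uses a Hann taper, a single full-length segment for 60-s windows, and
linear detrending — without detrending, the slow wander of heart-rate tone
leaks across all bands at this window length.  Band powers are trapezoidal
integrals of the density.  Age and sex are carried as metadata, not
features (the documented feature list sums to 120 without them); a model
consumer may append them explicitly.

Features that cannot be computed (empty slice, too few samples, HF = 0 for
the ratio) are NaN markers, never silent zeros; the tree learner routes
missing values natively and no imputation is performed anywhere.

The batch featurizer is vectorized over windows but computes the identical
statistics as the per-window functions; the test suite checks agreement.

## Classifier

Balanced bootstrap: each of *n* branches (default 64) gets the positives
resampled with replacement to their original count plus an equal number of
negatives drawn without replacement from a rotating shuffled pool, so
branches are exactly balanced and see diverse negatives.  Each branch
trains an independent gradient-boosted tree classifier (XGBoost; 400
estimators, learning rate 0.1, positive-class weight 1, subsample 0.9,
L2 = 2, L1 = 0, min child weight 3, max depth 8, binary cross-entropy with
probability output).  The ensemble score of a window is the arithmetic
mean of branch probabilities; the deployment decision threshold is 0.5.

Cross-validation is patient-grouped and seizure-balanced: subjects are
greedily assigned, in descending order of seizure count, to the fold with
the lightest seizure load (10 folds by default), so no subject straddles
folds and folds carry near-equal seizure numbers.

## Event-level evaluation

Scored windows at or above threshold (excluded windows never fire) are
chained greedily into alarms: a gap of more than 180 s from the previous
firing window's end starts a new alarm; anything closer merges.  A seizure
is detected iff at least one alarm overlaps `[onset, offset)`; an alarm
overlapping neither a seizure nor its 60-s buffers is a false alarm
(buffer-touching alarms are neither).  Sensitivity = 100 × detected /
recorded; FAR = false alarms per 24 monitored (wear) hours, buffers
included in the denominator.  FAR/sensitivity pairs over descending
thresholds form the operating curve; the selected threshold minimizes the
Euclidean distance to the (FAR 0, Sens 100%) corner on min-max-normalized
axes, with 0.5 as the degenerate-curve default.  Reports round sensitivity
to integer percent and FAR to two decimals.

The streaming monitor replays a record, scoring the trailing 60-s window
every 30 s with the same featurization code, skipping ticks with
insufficient trailing data and chaining alarms online; on an identical
window grid its alarms equal the batch path exactly.

A device-linearity utility regresses a test series on a time-aligned
reference (nearest-neighbor alignment to reference ticks) and reports the
maximum absolute residual as a percentage of the reference range; constant
offsets and gain are absorbed by the fitted line.

## Cohort physiome

Outside seizure time, each subject is summarized by the ten statistics of
seven variables — HR, SDNN (per 5-min epoch, then summarized), the three
ACC axes, ACC magnitude, GSR — a 70-column subject matrix (values on the
raw scale so developmental trends survive).  Day is [08:00, 20:00) and
night [21:00, 07:00) local clock; the unassigned hours 07–08 and 20–21
belong to neither.  A stacked ordinary-least-squares regression (one day
row and one night row per subject; response = period mean) on age in
months, sex (male = 0, female = 1) and period (night = 0, day = 1), with
intercept, quantifies developmental effects; per-period separate fits are
also available.  Day/night contrasts within age bands (0–1, 1–3, 3–5, >5
years) use two-sided Wilcoxon rank-sum tests on subjects' period means.
PCA min-max scales each column to [0, 1], mean-centers, and projects onto
the top three right singular vectors (constant columns dropped, incomplete
subjects dropped); loadings are orthonormal and explained-variance
fractions non-increasing.  The published normalization phrase mixes
"zero-mean" and "[0, 1]"; scaling then centering satisfies both readings
in sequence.

## Synthetic physiome generator

The generator's defaults encode the study conditions the analysis targets:

* ages uniform over 1–161 months; sexes balanced;
* resting HR 115 bpm through 12 months falling linearly to 80 bpm at 60
  months and flat beyond; a 5-bpm circadian term (cosine peaking at 14:00)
  for children over 12 months and zero for infants, reproducing the
  infant-flat day/night contrast;
* HR noise = AR(1) (SD 2 bpm, φ 0.95) + a slow two-scale wander (SD 8 bpm,
  φ 0.9995, the tens-of-minutes movement of heart-rate tone from feeding,
  crying and sleep-stage changes) + sinusoidal modulations at 0.1 Hz
  (3 bpm) and 0.25 Hz (2 bpm) so the derived RRI has controllable LF and
  HF band powers.  The slow wander matters doubly: it is what places
  seizure tachycardia partly *inside* the subject's central 90% so the
  percentile trim does not delete the entire in-event excursion;
* GSR baseline 8 µS at birth falling 0.03 µS/month (floor 1 µS), +0.5 µS
  by day, +0.3 µS for females, AR noise SD 0.6 µS;
* ACC axes = a slowly drifting unit-norm gravity orientation + 0.02 g
  sensor noise; activity bouts (Poisson, 4/h, mean 120 s) add 0.25 g
  dynamic acceleration and 25 deg/s gyration.  Resting magnitude sits near
  1 g, as a wrist-worn accelerometer reports;
* seizures: homogeneous Poisson at 5.6 events per 24 wear-hours (the
  cohort aggregate of 1,290 events over 5,543 monitored hours), clipped to
  wear time with a 180-s minimum inter-event gap; durations from the
  six-bin categorical (81.3 / 10.3 / 3.2 / 2.3 / 1.1 / 1.8% for <1, 1–2,
  2–3, 3–4, 4–5, >5 minutes), uniform within bin, the open last bin capped
  at 600 s;
* seizure signature within `[onset, offset)`: HR raised 25 bpm with its
  deviation from the local median shrunk by the suppression factor 0.4 and
  an extra 0.1-Hz modulation realizing an LF/HF gain of 2; GSR +1 µS; ACC
  +0.5 g and GYR +30 deg/s jerky noise bursts; exact return to baseline at
  offset;
* missing data as contiguous exponential-length spans (mean 2 min, 5% of
  time) shared across channels — transmission dropouts hit the whole
  device — plus non-wear spans (mean 30 min, 5%), both truncated to their
  coverage budget so short recordings keep the configured rates;
* fully deterministic under (seed, subject index); default monitored time
  24 h per subject (the study's mean monitored time is ~85 h; 24 h keeps a
  full circadian cycle at desk scale).

What the generator does **not** emulate: PPG waveform artifacts and
motion-induced optical noise, annotation latency or missed caregiver
annotations, pre-ictal physiology (signatures switch on exactly at onset),
inter-seizure dependence, wake/sleep architecture beyond the circadian
cosine, and any EEG ground truth.  Passing recovery tests therefore shows
the pipeline recovers the structure this generator encodes — not clinical
performance on real recordings.

## Problem sizes and effect sizes used in tests

The end-to-end recovery experiment uses a 40-subject cohort monitored 24 h
each (≈900 wear-hours, ≈190 seizures) with a 16-branch × 100-estimator
ensemble for the cross-validated run; ensemble-size sweeps (16×100 vs
64×100 vs 64×400) change pooled AUROC and event sensitivity by less than
half a point on this cohort, so the smaller configuration is the routine
experiment size.  The physiome recovery uses 24 subjects × 24 h.
Direction-contrast checks use long-duration events so windows lie fully
inside events.

Recovery and direction tests inject a 15-bpm tachycardia with suppression
factor 0.3 rather than the package-default 25 bpm.  The reason is
measurement physics, not modesty: a +25-bpm excursion sits almost entirely
above a resting child's 95th HR percentile, so the whole-recording trim
deletes nearly every in-event HR/RRI sample and with them the HRV
suppression the tests are meant to recover.  At +15 bpm a substantial
fraction of in-event samples survives the trim and all five direction
contrasts (HR, GSR, ACC magnitude up; SDNN, RMSSD down) hold at p < 0.01
through the full pipeline.

## Known limitations

* LF/HF (and VLF) at the 60-s window scale are leakage-dominated: the
  window offers 1/60 Hz resolution and the 1-Hz pseudo-RRI plus 5-sample
  smoothing leave little genuine HF power.  They are retained for schema
  fidelity; the in-event LF/HF elevation is demonstrable on the clean
  derived RRI but not reliably after full preprocessing.
* The whole-recording percentile trim removes the most extreme in-seizure
  samples by construction; in-event statistics are therefore truncated at
  the subject's 5th/95th percentiles.  Detection rests on the joint
  pattern (truncated HR/RRI shift, GSR rise, motion burst, HRV
  suppression), not on raw peak amplitude.
* Pseudo-RRI HRV is not beat-accurate HRV (see above).
* The event-level false-alarm rate at the fixed 0.5 threshold depends on
  score calibration of the balanced ensemble, which intentionally ignores
  the true class prior; the operating-curve machinery exposes
  better-calibrated operating points.
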