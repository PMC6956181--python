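# Methods

## The measurement model

All intensity measurements operate on mono audio normalized to [-1, 1] and
use non-overlapping 100 ms rectangular frames — the native resolution of the
clinical metering application this package re-implements. The meter unit
**U** is defined as 16-bit PCM sample magnitude: a sample `x` contributes
`|round(x * 32767)|` U. Per frame, **VU** is the mean of these magnitudes
and **PPM** their maximum; both therefore lie in [0, 32767] and scale
linearly with amplitude (to ±1 U of rounding). This definition is declared,
not inferred: the original application documented only that U is neither dB
nor Hz, and 16-bit magnitude reproduces the printed orders of magnitude
(recording-level VU up to a few thousand U, PPM up to ~13 000 U, both below
32 767). The spectrogram uses a Hann window per 100 ms frame, zero-padded to
4096 points, scaled so a full-scale sinusoid peaks near 32 767 U (Hann
scalloping of up to ~15 % on off-bin tones is accepted). F0 is estimated per
frame by FFT-based autocorrelation restricted to a search band (default
150–800 Hz) with parabolic peak interpolation — the simplest method that is
exact for the harmonic stimuli the generator produces; healthy newborns
phonate near 250–450 Hz.

True broadcast PPM ballistics (attack/release time constants), perceptual
loudness and cepstral features are out of scope.

## Cry-language segmentation

Segmentation runs on the VU trace, not the raw audio, so boundaries are
quantized to 100 ms. A frame is cry-active when its VU exceeds
`max(50 U, 5 % of the trace maximum)` (configurable); the absolute floor
keeps background noise unvoiced, the relative part adapts to the
recording's loudness. A **word** is a maximal active run of at least 200 ms;
consecutive words separated by silence ≤ 1 s (an inhalation gap) share a
**sentence**; sentences separated by ≤ 3 s share a **phrase**. These pause
thresholds are design defaults — the source study never quantified its
pause criteria — and the synthetic presets are constructed to be
unambiguous under them (0.3 s < 1 s < 1.5 s < 3 s < 4 s). A sentence's
duration runs from its first word's onset to its last word's end.

Intervals are half-open, coordinates in seconds, frame indices 0-based.

## Intensity statistics and tests

Recording-level intensity summaries are restricted to voiced frames (frames
inside detected words): a whole-recording minimum would always be silence
(≈0 U), whereas the study's minima are nonzero, which implies cry-active
frames. The discriminating statistic, **mean minimums**, is: per recording,
the minimum voiced-frame meter value; then the group mean of those minima.
Group comparisons use the two-sided Student (pooled) *t*-test at α = 0.05
with a 95 % CI on the mean difference; `t_test_auto` switches to Welch when
the sample-variance ratio exceeds 4 (with a warning, never silently). The
two primary endpoints (VU and PPM mean minimums) are tested without
multiple-testing correction, matching the original analysis; degenerate
inputs with zero variance in both groups and equal means return p = 1 by
convention, and unequal constant groups are an error. Whether sentence-level
tables are computed per sentence or per recording is ambiguous in the source
material; this package pools per-sentence values and summarizes per-recording
minima, both exposed so either reading can be computed.

## The synthetic cry generator

The generator is the package's study stand-in: no recordings are deposited,
so both cohorts are emulated by a scripted model rich enough to exercise
every downstream feature (VU/PPM levels, spectra, F0 band, burst
structure) and nothing more — no vocal-tract or formant modeling, no
pathological cry types.

**Planning.** A recording's total duration is uniform on 30–90 s (the study
protocol's recording window). Words-per-sentence counts are drawn from a
*truncated discrete normal* — a normal draw rounded, then clipped to the
published range — because mean, SD and range are exactly what the study
reports (M: 9.45 / 3.381 / [4, 18]; C: 7.65 / 2.485 / [4, 14]). Word
durations are normal (1.0 ± 0.3 s, clipped to [0.5, 2]); the recording's
first word uses the published first-word distribution (1.21 ± 0.5 s,
clipped to [0.5, 2.9]). Pauses are fixed: 0.3 s inhalation gaps within a
sentence, 1.5 s between sentences, 4 s between phrases — strictly ordered so
segmentation is well-posed. Whole sentences are appended while they fit the
duration budget and the first overflowing sentence ends the plan; this
sentence-granular truncation keeps completed sentences distributed exactly
as drawn (mid-sentence truncation would bias words/sentence downward by
roughly one word per recording). If not even one word fits, a single
truncated word is emitted.

**Intensity.** Per-word peak amplitudes are specified in peak-reading U
(peak sample × 32 767) and drawn lognormal around the group's published
typical level (M 1659.973 U, C 2189.202 U) with CV 0.5 — the study reports
no dispersion for intensity, so the CV is a flagged free parameter — and
clipped at 3× the mean. One randomly chosen word per recording is instead
forced near the group's minimum level (M 343 U, C 598 U), placing the
per-recording minimum at the published group level. The 3× clip guarantees
the quiet word always clears the relative activity threshold
(0.05 × trace max ≤ 0.075 × mean < quiet-word level), so zero-noise
segmentation recovers the planned structure exactly. The peak-reading
convention follows the PPM statistics; the corresponding VU minima
(11/24 U, i.e. 0.03 % of full scale) are physically below any workable
activity threshold and are used directly — not through rendering — where
the mean-minimum significance test is replicated.

**Rendering.** Each word is a harmonic stack at its per-word F0 (normal,
350 Hz ± 5 %, 8 harmonics with 1/k roll-off), normalized so a linear
100 ms attack / 100 ms decay envelope reaches exactly the scripted peak;
elsewhere Gaussian noise at `noise_rms` (default 10⁻³, ≈26 U, below the
50 U activity floor). Output is clipped to [-1, 1]. The 22 050 Hz default
rate comfortably covers F0 ≤ 450 Hz plus 8 harmonics.

**What passing tests show — and don't.** Round-trip exactness at zero noise
shows the measurement chain is self-consistent, and parameter recovery shows
the pipeline estimates are unbiased at realistic sizes. It does not show
robustness to real maternity-ward acoustics: reverberation, monitor alarms,
overlapping voices, or cry phenomena the model omits (glide, vibrato,
biphonation, voiced inhalations). Classifier accuracies on synthetic cohorts
likewise reflect the constructed group separation, not clinical
discriminability.

## Classifiers and evaluation

Instances are the first 300 VU or PPM frames (30 s) per recording, raw U
values (no normalization by default), right-padded with 0 U — the only
meter-neutral padding — for shorter recordings; labels are the cohort
letters. Datasets round-trip through standard ARFF.

* **IB1** — single Euclidean nearest neighbor, first-found tie-break.
* **Random Tree** — unpruned tree choosing the best of
  `ceil(log2(p) + 1)` randomly sampled attributes per node by information
  gain (via scikit-learn's tree with `max_features`); pure leaves memorize
  duplicate-free training data.
* **Decision Table** — attributes discretized into 10 equal-width bins over
  the training range; greedy forward selection maximizes leave-one-out
  accuracy of the lookup table (training accuracy breaks LOO ties, so
  separable data are still memorized); unmatched rows fall back to the
  majority class.
* **NNGE** — incremental nearest-generalized-exemplar learner: axis-aligned
  hyperrectangles grown over same-class neighbors, extensions rejected if
  they would swallow an opposite-class instance, and rectangles split along
  their widest dimension when a new opposite-class instance lands inside —
  which keeps the learner consistent on its training data.

These are documented simplified-faithful variants of the classic Weka
algorithms; exact numeric parity with Weka is a non-goal. The four error
indicators reported alongside accuracy are the canonical quartet — MAE and
RMSE over class-probability vectors against one-hot truth, and RAE/RRSE
normalizing by a prior-probability baseline fitted on the same training
portion — the standard reading of the study's loosely translated indicator
names. (The study's category labels for IB1/NNGE appear swapped — "1B1"
under rules, NNGE under lazy learners — and one of its published
correct/incorrect pairs does not sum to 100 %; here the complement
invariant `correct + incorrect = 100 %` is enforced.) Protocols: training
(fit and test on the full set), stratified seeded 10-fold CV with metrics
pooled over folds, and a stratified seeded 75/25 split.

## Orchestration, filters, determinism

Cohort inclusion mirrors the study: group M requires gestational age 38–42
weeks and Apgar exactly 10; group C requires GA ≥ 38 and Apgar 7–10. The
recording-quality filter estimates SNR as the dB ratio of voiced- to
unvoiced-frame mean VU and excludes below 10 dB; recordings with no
detected words — or with *no unvoiced frames at all* (noise loud enough to
saturate the activity detector leaves no noise floor) — are excluded, which
makes inclusion monotone non-increasing in added noise. Recording-protocol
provenance (first 24 h, closed incubator, 15 cm microphone distance) is
metadata only and never gates computation.

Every source of randomness derives from one master seed through
`numpy.random.SeedSequence`, so cohorts, studies and evaluations are
bit-reproducible; artifacts are stamped with a config hash and the seed.

## Problem sizes

The acceptance script synthesizes the full-size cohorts (101 + 72
recordings of 30–90 s at 22.05 kHz, ≈750 sentences) for structure
recovery, 100 replicates for the significance checks, and a 20 + 20 cohort
for the training-accuracy checks; the test suite uses 6–30 recordings of
8–20 s per case. These sizes give sampling errors well inside the stated
tolerances (e.g. SE ≈ 0.17 words/sentence for the control cohort).

## Known limitations

* Segmentation resolution is one meter frame (100 ms); word durations
  shorter than 200 ms are invisible by design.
* The sentence-duration table of the source study carries ambiguous units;
  presets treat it as seconds but no conclusion rests on it.
* The Decision Table's equal-width binning is a design choice; exact-match
  tables over continuous attributes would degenerate to the majority class.
* Group presets differ in structure *and* loudness, so synthetic
  classification results conflate both cues, as the real study's features
  presumably did.
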