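# cryspect

Acoustic analysis of the newborn cry as a language. The package implements a
complete, tested pipeline for a two-cohort neonatal cry study — healthy
controls (group **M**) versus newborns delivered with a tight nuchal cord
(group **C**) — built for researchers in biomedical acoustics and neonatology
who want the measurement chain to be reproducible without access to clinical
recordings.

## What it computes

* **Intensity metering.** For every non-overlapping 100 ms frame of a mono
  recording: **VU** (volume unit meter, the frame's mean intensity) and
  **PPM** (peak program meter, the frame's maximum), expressed in the meter
  unit **U** — one count of 16-bit PCM sample magnitude, so full scale is
  32 767 U — plus a Hann-windowed magnitude spectrogram in the same units and
  an autocorrelation F0 track over the neonatal phonation band
  (≈250–450 Hz in healthy newborns).
* **Cry-language segmentation.** On the VU trace: a *word* is one voiced
  expiration (maximal run of cry-active frames), a *sentence* is a cry burst
  (words separated by short inhalation gaps), a *phrase* is a group of
  bursts. Per recording: sentence durations, words/sentence, first-word
  duration.
* **Cohort statistics.** Group tables (N, mean, SD, min, max) and two-sided
  Student *t*-tests (α = 0.05, 95 % CI; Welch variant available) on the
  discriminating statistic: the **mean minimums** — per recording, the
  minimum voiced-frame meter value; then the group mean of those minima.
* **Classification.** 300-attribute instances (30 s × 10 frames/s of VU or
  PPM) with ARFF import/export; IB1 (1-nearest-neighbor), unpruned Random
  Tree, Decision Table, and NNGE classifiers; training / stratified 10-fold
  CV / 75 % split protocols; accuracy, MAE, RMSE, RAE, RRSE and the
  confusion matrix.
* **Synthetic cohorts.** Because no recordings are deposited, a scripted
  generator synthesizes both cohorts: harmonic-stack words (1/k roll-off,
  attack–sustain–decay envelope) laid out by group-specific structure
  distributions (e.g. words/sentence 9.45 ± 3.381 in [4, 18] for controls,
  7.65 ± 2.485 in [4, 14] for the nuchal-cord group), with scripted ground
  truth for round-trip verification.

## Worked example

```sh
$ cryspect run --out study_out --seed 5 --n-m 3 --n-c 3
config 8d5eaf24785cb930, seed 5
group M: included 3/3; words/sentence 10.80
group C: included 3/3; words/sentence 7.44
first word duration 0.98 s
VU mean-minimum t-test: p=0.008352 significant=True
PPM mean-minimum t-test: p=0.0004617 significant=True
```

Three recordings per group were synthesized, all passed the inclusion
(gestational age / Apgar) and noise-quality filters, and segmentation
recovered group-typical structure (controls utter more words per sentence).
Even at this tiny size the nuchal-cord group's per-recording minimum
intensities are significantly *louder* than the controls' — the study's
headline effect: affected newborns never get as quiet between cry peaks.
`study_out/` holds the per-recording measurement bundles (WAV + VU/PPM/
Spectrum text traces), segmentation files, group tables, ARFF datasets and
classifier reports, each stamped with the config hash and seed.

The same pipeline is available as a library:

```python
from cryspect import group_preset, generate_cohort, segment_waveform
from cryspect.linguistics import structure_stats

records = generate_cohort(group_preset("M"), group_preset("C"), 5, 5, seed=0)
stats = structure_stats(segment_waveform(records[0].waveform))
print(stats.words_per_sentence, stats.first_word_duration)
```

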