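# ppgscreen

Pulse-wave analysis and two-stage cardiovascular disease screening from
photoplethysmography (PPG).

A fingertip pulse oximeter records the pulsatile blood-volume waveform of
every heartbeat. The shape of that pulse — how fast it rises, where the
dicrotic notch sits, how much area lies under the diastolic limb — carries
information about arterial stiffness and cardiovascular health.
`ppgscreen` implements a complete screening pipeline around this signal,
for researchers who want a reproducible, testable reference implementation
with known ground truth:

1. **Synthetic cohorts** (`ppgscreen.synthgen`): PPG recordings built from a
   two-Gaussian pulse model (systolic + diastolic component) with
   class-conditional morphology for healthy subjects and five CVD classes
   (ACS, CVA, DVT, HF, AF), per-beat jitter, respiration-band baseline
   wander, white noise, and *analytic* ground-truth landmarks per beat.
2. **Preprocessing** (`preprocess`): zero-phase elliptic band-pass
   (0.6–15 Hz at 120 Hz sampling) and beat segmentation at pulse feet.
3. **Fiducials** (`fiducials`): systolic peak, dicrotic notch (with an APG
   e-wave fallback for notch-less "shoulder" pulses) and the a/b/e waves of
   the acceleration plethysmogram (second derivative).
4. **Features** (`features`): the 24 per-beat time-domain features —
   amplitudes (SA, notch), intervals (ΔT, pulse interval, crest time,
   systolic/diastolic time, PTT), pulse width, areas (total, IPA),
   augmentation/reflection indices, stiffness index SI = height/PTT, time
   ratios T1–T3 and APG ratios (b/a, e/a, (b−e)/a) — aggregated per subject
   as mean and sample variance.
5. **Classification** (`mlpipe`): greedy stepwise *wrapper* feature
   selection (the subset is chosen by the cross-validated accuracy of the
   very classifier that will use it) and a two-stage cascade — stage 1
   screens healthy vs CVD on feature means + variances + demographics;
   stage 2 types the disease among the positives on means only. Seven
   classifier families are provided (decision tree, random forest,
   RIPPER-style and PART-style rule learners, MLP, k-NN, Gaussian naive
   Bayes), with minority classes replicated inside training folds only so
   cross-validation stays leak-free.
6. **Statistics** (`statreport`): per-feature Welch t-test screen
   (healthy vs CVD, α = 0.05) and deterministic CSV/text report tables.

## Worked example

```sh
python examples/04_select_and_classify.py
```

builds a ~92-subject cohort, extracts features, and runs both stages:

```
stage 1 (healthy vs CVD)
  selected: IPA_mean
  10-fold CV accuracy: 100.00%
  per-class recall: CVD 1.000, Healthy 1.000
  subjects leaked across folds: 0

stage 2 (5-way CVD typing, means only)
  selected: dT_mean, e_mean
  10-fold CV accuracy: 100.00%
```

The wrapper settled on the inflection-point area ratio (diastolic/systolic
area) for stage 1 — the synthetic CVD classes have attenuated diastolic
waves, so IPA separates them cleanly — and on the peak-to-peak interval
plus the APG e-wave amplitude for disease typing. The leakage line is the
audit that no subject (or replicated copy of one) appears in both the
train and test partition of any fold. See `examples/01`–`03` for cohort
simulation, single-subject feature extraction and the t-test screen.

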