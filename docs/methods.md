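# Methods

## The pulse model and what the generator emulates

Each beat is the sum of two Gaussian components on a zero baseline:

    p(t) = A_s exp(-(t - c_s)² / 2w_s²) + A_d exp(-(t - c_d)² / 2w_d²)

with systolic amplitude/center/width (A_s, c_s, w_s), diastolic
(A_d, c_d, w_d) and a beat period T. This is the simplest shape that
exhibits every landmark the feature catalogue needs — a systolic peak, a
dicrotic notch between the components, a diastolic wave, and a/b/e waves in
the second derivative — while keeping all of them analytically computable.
Recordings are *superpositions* of consecutive beats (each beat's tails
extend under its neighbours), so the signal is smooth at beat boundaries
and the pulse foot is a genuine local minimum of the continuous model, as
in real PPG. Ground-truth landmark times are found by bounded numerical
optimisation of the continuous model (grid bracketing + refinement to
1e-10 s), so they are independent of the sampling grid; the first and last
beat of a recording have no well-defined foot on both sides and carry no
ground-truth entry.

Per-beat variation: period jitter (sd 0.02 s), multiplicative amplitude
jitter (3%), sinusoidal baseline wander (0.1 a.u. at 0.25 Hz — inside the
respiration band the band-pass removes) and additive white noise
(sd 0.02 a.u.). Default cohort: 120 s per subject at 120 Hz, class counts
Healthy 200, ACS 63, CVA 50, DVT 23, HF 13, AF 13. (The narrative total of
"200 healthy and 160 CVD" is inconsistent with these per-class counts,
which sum to 162; the per-class counts are taken as authoritative, giving
362 subjects.)

Class-conditional morphology encodes the clinical picture that arterial
stiffness attenuates the diastolic wave: healthy pulses have A_d/A_s ≈
0.45 and a short crest time; ACS/CVA/DVT have reduced diastolic amplitude
(0.18–0.28) and longer crest times; HF has a near-absent diastolic wave
(A_d ≈ 0.05, usually no true notch — exercising the absent-notch path);
AF is fast (T ≈ 0.62 s). Demographics are drawn per class (CVD classes
older, more smokers, more hypertension, lower SpO2), with BMI = weight/height²
by construction. The between-subject sd of each morphology parameter is
small relative to the class separations, which makes the default cohort
*strongly separable* — deliberate: it is the configuration under which the
end-to-end achievability checks run. What the generator does **not**
emulate: real pulse-shape heterogeneity within a class, motion artifacts,
arrhythmic beat-to-beat morphology changes, sensor nonlinearity, or any
overlap between classes beyond Gaussian parameter jitter. Passing tests
therefore demonstrate that the pipeline recovers what it is supposed to
recover and can reach screening-grade accuracy on separable data — not
that comparable accuracy would be reached on clinical recordings.

## Preprocessing

Elliptic band-pass, 0.6–15 Hz edges, order 4, 0.05 dB pass-band ripple,
40 dB stop-band, applied forward–backward (`sosfiltfilt`) so fiducial
timings suffer no group delay. The ripple default is deliberately small:
with 0.5 dB ripple the pass-band shaping measurably displaces the shallow
notch minimum of attenuated-notch pulses (recovery on ACS-like pulses fell
from ~99% to ~58% at 2-sample tolerance); at 0.05 dB the morphology is
preserved and the 0.25 Hz respiration tone is still attenuated by ~78 dB
after the two passes. Note the elliptic stop band is equiripple, so the DC
gain sits at the −40 dB floor rather than at exactly zero.

Segmentation finds systolic peaks first (prominence ≥ 0.5 × the 10–90
percentile spread, ≥ 0.25 × min_beat_s apart) and places each onset at the
signal minimum between consecutive peaks. Peak-first detection is what
keeps the shallower dicrotic-notch minima from being mistaken for beat
boundaries. Gates: beat duration within [0.33 s, 2.0 s] (30–180 bpm) and
peak rise ≥ 10% of the record's median; beats are half-open sample
intervals `[onset, end)`.

## Fiducials

* Systolic peak: global maximum of the beat, earliest index on ties;
  a boundary maximum means no pulse and is rejected.
* APG: Savitzky–Golay second derivative (window 11 samples at 120 Hz,
  polynomial order 3, auto-shrunk with a warning on short beats).
  a = first prominent APG maximum, b = first prominent minimum after a,
  e = first prominent maximum later than 50 ms after the systolic peak
  (prominence threshold 5% of the APG range). The 50 ms exclusion is a
  physiological bound that also prevents smoothing side-lobes of the apex
  curvature spike from being read as e.
* Dicrotic notch: lowest local minimum in (t_sys, t_sys + 0.4 × beat
  duration]. When no minimum exists but the descending limb flattens
  locally (an interior local maximum of the smoothed first derivative —
  the "shoulder" signature), the APG e-wave time is used instead; when
  both fail the notch is reported absent, which is a valid outcome and
  leaves the notch-dependent features missing for that beat.

The pulse foot deserves a caveat: on pulses whose diastolic limb has
decayed to a flat runoff before the next upstroke, the foot minimum is a
broad, shallow basin. Both the analytic ground truth and any detector
place it only to within several samples (~8 at 120 Hz on the default
morphologies), so onset-anchored intervals (crest time, pulse interval)
are intrinsically less precise than peak- and notch-anchored ones (ΔT,
PTT), and the test suite holds them to correspondingly different
tolerances (8 vs 2 samples).

## Features

The 24 per-beat features follow the standard pulse-wave definitions; all
amplitudes and areas are measured above the per-beat baseline, defined as
the amplitude at the beat onset (band-passing removes slow drift but not
residual per-beat offsets). Pulse width uses sub-sample linear
interpolation at both half-height crossings. Areas are trapezoidal with
the systolic/diastolic split sharing the notch sample, so
total = systolic + diastolic holds exactly. Systolic time is defined
onset→notch, which makes systolic time = CT + PTT and hence T2 = T1 + T3
exact identities — these, with AI_amp + RI = 1, are the algebraic
invariants the acceptance suite checks to 1e-9. ΔT is computed only across
truly consecutive accepted beats (shared boundary); it is missing for the
last beat, and T1–T3 with it. SI uses height in metres over PTT in
seconds (m/s).

Aggregation: feature-wise NaN-aware mean and sample variance (n−1) over
beats; a subject needs ≥ 5 valid beats. The subject row also logs the
notch-presence fraction and a derived pulse rate (60/mean ΔT) as a
cross-check against the device-reported pulse rate, which is the one used
as a feature.

## Selection and classification

Stage 1 (healthy vs CVD) uses all feature means + variances +
demographics (60 columns); stage 2 (5-way typing, CVD subjects only) uses
means + demographics (36 columns) — the variance columns are excluded by
schema there. Feature subsets come from a greedy stepwise wrapper: add
(forward) or remove (backward) the candidate that maximises the wrapped
classifier's stratified 10-fold CV accuracy, stopping when no step
improves by more than the tolerance (default: any strict improvement).
Ties go to the earliest candidate in declaration order (features in
catalogue order, then demographics).

Class imbalance is handled by whole-subject replication of minority
classes up to the majority count (⌈n_max/n_c⌉ copies, truncated). The
default mode replicates **inside each training fold only**; the
alternative `replicate-global` mode balances before splitting, which puts
copies of one subject on both sides of a fold — the leakage audit exposes
exactly this, and the test suite demonstrates both behaviours. Missing
values are imputed with training-fold medians; k-NN and the MLP are
standardised on training data inside the fold.

The seven classifier families are scikit-learn estimators where one
exists (pruned decision tree with min leaf 2 and ccp_alpha 0.005; random
forest with 100 trees; one-hidden-layer MLP of size
(features+classes)/2, max 500 epochs; 1-NN with standardisation; Gaussian
naive Bayes). The two rule-based families are implemented natively:
a RIPPER-style sequential-covering learner (classes rarest-first,
conjunctive rules grown by FOIL gain over quantile thresholds, majority
default) and a PART-style learner (repeatedly fit a depth-3 tree on
uncovered instances and take its most populous leaf as a rule).

Reported stage accuracies follow the select-then-cross-validate protocol:
the wrapper chooses the subset and that subset's 10-fold CV accuracy is
reported. This matters for naive Bayes in particular: the 24 features
derive from a handful of underlying morphology parameters and are strongly
correlated, so full-feature NB multiplies the penalty of a single
parameter deviation many times over and is unstable (measured stage-1
accuracy varied between 72% and 98% across cohort seeds, versus a stable
≥ 97% on the selected subset).

## Statistics

Per-feature Welch (unequal-variance) two-sample t-tests, healthy vs CVD,
α = 0.05. The significance flag is uncorrected — the screen is
descriptive — and a Benjamini–Hochberg adjusted column is emitted
alongside. Degenerate identical groups report t = 0, p = 1. The type-I
calibration check verifies the screen flags ≈ 5% of features under a
global null (3σ binomial band over 200 replicates × 24 features).

## Problem sizes used by the validation suite

Fiducial recovery runs on 60 subjects (10 per class) at 120 s / 120 Hz
with jitter, wander and noise all zero; feature identities on 1,000
random morphologies drawn across the physiological range; selection
soundness on 20 seeded datasets of n = 100 with one planted 2-sd feature
among 10 noise features; the end-to-end check on the full 362-subject
composition at 60 s per recording (the shorter recording halves synthesis
and extraction cost without changing the per-subject feature
distributions materially — aggregates are means over ~60 beats instead of
~120).

## Known limitations

* The two-Gaussian pulse cannot produce class-overlapping, multi-modal or
  pathologically irregular morphologies; accuracy figures on it are
  achievability statements only.
* The foot/onset imprecision above propagates into CT, pulse interval and
  the areas' integration limits.
* The rule learners are compact re-implementations of their families, not
  re-creations of any specific third-party build; their rule sets are
  deterministic but simpler than full RIPPER/PART (no pruning-set
  optimisation, no rule revision passes).
* `replicate-global` mode exists to mirror balance-then-validate
  protocols and intentionally leaks; accuracies measured in that mode are
  optimistic and should be read as such.
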