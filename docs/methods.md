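# Methods

## The task and the model

A phonocardiogram from one auscultation site (left apex, left base or right
side; 15 s, mono) is graded on the reduced murmur scale {none, soft,
moderate, loud, thrilling}. The recording is transformed into a normalized
log-spectrogram, fed through a bidirectional gated-recurrent-unit (GRU)
network, mean-pooled over time, and mapped to 5 class logits. Softmax
cross-entropy treats the grades as unordered classes; the ordinal structure
is exploited only at read-out time, through the derived scores
`1 − P(none)` (murmur of any intensity) and `P(loud) + P(thrilling)` (the
staging score). Training uses Adam; the entire network stack — forward
pass, backpropagation through time, optimizer — is a compact NumPy
implementation, chosen so the package trains in minutes on one CPU with no
deep-learning framework dependency.

Transfer learning follows the head-surgery recipe: a base model with a
2-class head is first trained on a binary murmur-present task; its final
weight and bias are then cleared and replaced by a zero-initialized 5-class
head (so immediately after surgery every input maps to the uniform
distribution, 0.2 per grade), and the *whole* network is fine-tuned — no
layer is frozen. In this package the pretraining corpus is synthetic
(loud-vs-none recordings at low noise); the downstream interface is
identical to one pretrained on a clinical corpus.

Fine-tuning uses patient-level 5-fold cross-validation: folds partition
dogs, never recordings of one dog, and are stratified by each dog's maximum
grade so no fold loses a class. Each fold model early-stops on its held-out
fold's cross-entropy (patience 10 epochs, best weights restored). How the
fold models should predict at test time is an open choice; the package
averages their softmax outputs, the standard ensembling resolution, and the
prediction API treats the 5 models as one ensemble.

## Key parameters

| parameter | default | notes |
|---|---|---|
| sample rate | 4000 Hz | heart sounds and murmurs live below ~1 kHz |
| recording length | 15 s | the clinical recording protocol |
| spectrogram (features default) | 50 ms window, 20 ms hop, 20–800 Hz, per-recording z-score | resolves S1/S2 (<150 Hz) vs murmur band (100–400 Hz) |
| spectrogram (model default) | 100 ms window, 80 ms hop | ~186 frames per recording; shorter sequences make CPU BPTT fast with no measurable accuracy cost on synthetic data |
| GRU | 1 bidirectional layer, hidden 48 | small enough for minutes-scale fine-tuning; configurable |
| optimizer | Adam, lr 5e-3, batch 64, ≤40 epochs | |
| evaluation | 50 repeats, 1000 bootstrap draws, 95% CIs | tests and examples scale these down (typically 10/200 or smaller); CI width scales as expected |
| staging threshold | 0.5 on `P(loud)+P(thrilling)` | equivalent to "a predicted loud or thrilling murmur decides B2"; exposed as config because the operating point is a clinical trade-off |

## Synthetic data: what it emulates and what it does not

Each beat contributes an S1 transient (damped sinusoid, 80–110 Hz, ~70 ms)
and an S2 transient (110–150 Hz, ~50 ms, 0.8× amplitude) at the configured
heart rate; systole is fixed at one third of the beat interval. A murmur is
Gaussian noise band-passed to 100–400 Hz, gated over systole (or the whole
cycle for the continuous shunt murmur of patent ductus arteriosus), with
RMS relative to S1 of 0.4 (soft), 1.0 (moderate), 2.0 (loud) and 2.5 plus a
40–75 Hz component (thrilling) — ordering the grades exactly as the clinical
definitions do, with clear margins. White ambient noise (RMS 0.02 relative
to S1) is added and the waveform is peak-normalized.

The cohort generator draws diagnosis, ACVIM stage, per-site Levine grades,
demographics, echo metrics and medication flags with marginals taken from
the published study tables: disease prevalences and per-disease grade and
point-of-maximal-intensity distributions from the diagnosis table, and
stage-conditional left-apex grades, ages, weights, body condition, sex,
pimobendan and arrhythmia rates from the MMVD staging table. Continuous
variables are log-normal matched to the printed median and interquartile
range. Echo metrics are resampled until they respect the stage definition
(B2 satisfies both thresholds, A/B1 fail at least one). For MMVD the left
apex is the point of maximal intensity and carries the stage-drawn grade;
other sites are 1–3 Levine levels quieter. For other diseases the maximal
site follows the printed location distribution.

What passing tests therefore show: the pipeline recovers grades it planted,
respects the protocol's leakage and balance guarantees, and its staging
score separates B1 from B2 as well as the grade–stage association allows.
What they cannot show: robustness to real acoustic variability — respiratory
and handling noise, stethoscope transfer functions, arrhythmic beat timing
(arrhythmia is a metadata flag only), within-grade loudness overlap, and
inter-observer grading disagreement are all absent from the generator, so
synthetic accuracy overstates clinical accuracy by construction.

## Split algorithm

Pocock–Simon range minimization with equal weights over six variables
(recruitment site; disease group MMVD/normal/other; heart rate and body
weight in cohort terciles; maximum murmur intensity on the reduced scale;
BCS < 5 vs ≥ 5; missing values form their own stratum). Arm size acts as a
dominant term: when the arms differ the patient joins the smaller one, so
|train| − |test| never exceeds 1. Ties are broken by a seeded coin flip.
Because the sequential pass is greedy, processing order can strand avoidable
imbalance (e.g. both members of an identical covariate pair in one arm); a
deterministic first-improvement swap pass (train↔test exchanges at fixed
arm sizes) removes it. The sequential core is online — assigning later
patients never changes earlier assignments — while the published split
quality refers to the polished result.

## Evaluation machinery

- **Repeated nested evaluation.** Each repeat draws a fresh minimized split
  from a per-repeat seed, re-runs head surgery from the fixed pretrained
  base, fine-tunes on the training arm only and scores only the test arm.
  With balanced 50/50 splits each patient appears in the test arm in
  exactly half the repeats on average.
- **ROC.** Empirical curves via scikit-learn; tied scores collapse to
  single vertices so the trapezoid AUC equals the pair-counting statistic
  with ties worth 1/2 (verified against an exact rational oracle). Curves
  are combined by vertical averaging: linear interpolation onto a 101-point
  FPR grid, mean and percentile band per grid point, AUC summaries from the
  per-curve AUCs.
- **Bootstrap.** Percentile CIs from patient-level resampling with
  replacement within each run, draws pooled across runs — patients, not
  recordings, are resampled to respect within-dog correlation. Degenerate
  resamples (statistic undefined) are redrawn. No normality assumption;
  BCa is deliberately not used.
- **Grading metrics.** Micro-averaged exact accuracy, within-one-grade
  rate, and a 5×5 confusion matrix with algorithm predictions in rows and
  expert grades in columns, each non-empty column normalized to 1.
- **Operating points.** On pooled scores: the "sensitive" point maximizes
  specificity subject to a sensitivity floor, the "specific" point the
  converse; targets are configuration.

## Numerical and degenerate-input choices

- Log compression uses `log(|X| + floor)` with floor 1e-6; an all-zero
  waveform maps to a constant `log(floor)` spectrogram. Amplitude scaling
  shifts pre-normalization values by `log c` (exactly, in the limit of a
  negligible floor) and cancels under z-scoring.
- Frames are half-open windows from sample 0 with a symmetric Hann taper; a
  trailing partial frame is dropped. Time-reversing a recording reverses
  the frame order with per-frame magnitudes preserved.
- Sigmoid inputs are clipped at ±60 to avoid overflow; softmax subtracts
  the row maximum.
- Seed handling: one global seed hash-derives per-stage seeds (stage-name
  SHA-256), cohort generation spawns per-dog child seeds, and per-repeat
  split/training seeds come from a spawned seed sequence — re-running any
  configuration reproduces outputs bit-for-bit.
- `GradeDistribution` enforces non-negativity and unit sum to 1e-6;
  ensemble outputs are renormalized before constructing one.
- Staging: C/D (congestive heart failure) is an input label, assigned
  clinically, never computed; a normal heart ≥ 15 kg receives stage "none"
  (the at-risk stage A is defined only below 15 kg); B1/B2 classification
  without a left-apex recording is an error, not an imputation.

## Problem sizes used in tests and the acceptance script

Training-based checks run on a 200-dog cohort (600 recordings, 50/50 split,
5 folds) for grading recovery and a fresh 400-dog preclinical cohort for
staging; protocol invariants use 10 repeats on a 16-dog cohort with a small
network plus 50 minimized splits of a 756-dog cohort; the bootstrap
calibration uses 200 simulations of 100 samples with 300 draws. These sizes
were chosen so the whole suite runs in minutes on one CPU while keeping the
statistical checks comfortably powered.

## Known limitations

- The pretrained base is a surrogate trained on synthetic audio; transfer
  gains over training from scratch are not themselves a claim this package
  tests.
- Cross-entropy ignores grade order during training; an ordinal loss might
  grade better but would depart from the modelled pipeline.
- The generator's grade brackets are nearly non-overlapping in murmur RMS,
  making the synthetic task easier than clinical grading; headline clinical
  metrics (e.g. AUCs near 0.9 on real dogs) are not reproducible here and
  are not claimed.
- Thrilling murmurs are defined by a palpable thrill, which audio cannot
  carry; the generator's sub-80 Hz surrogate component is a modelling
  convenience.
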