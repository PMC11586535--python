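# caninepcg

Machine grading of heart murmurs in dog phonocardiograms and staging of
preclinical myxomatous mitral valve disease (MMVD).

Auscultation is the front line of canine cardiology: the presence and
intensity of a heart murmur are sensitive indicators of MMVD — the most
common cardiac disease of adult dogs — and of congenital diseases such as
pulmonic and aortic stenosis. Intensity is scored on the 6-level Levine
scale (I–VI), usually collapsed to a reduced scale of **soft** (I/II, quieter
than the S1/S2 heart sounds), **moderate** (III, comparable), **loud** (IV,
louder) and **thrilling** (V/VI, palpable thrill), plus **none**. In
preclinical MMVD the treatment decision hinges on the echocardiographic
distinction between stage B1 and stage B2 (LA/Ao ≥ 1.6 **and**
LVIDDN ≥ 1.7, where LVIDDN = LVIDD(cm)/weight(kg)^0.294): stage B2 dogs
benefit from pimobendan. Expert-quality grading is scarce in first-opinion
practice, which motivates an algorithm that grades electronic-stethoscope
recordings automatically.

`caninepcg` is for researchers and engineers who want to build, probe or
extend such a pipeline without access to a clinical recording archive. It
provides, end to end:

- **Synthetic data** — phonocardiograms with damped-sinusoid S1/S2
  transients and band-limited (100–400 Hz) systolic murmur noise whose RMS
  relative to S1 encodes the reduced grade, and cohorts (demographics,
  per-site Levine grades, echo metrics, medication flags) whose marginals
  mirror the published study tables.
- **Features** — normalized log-spectrograms (`scipy.signal`).
- **Model** — a bidirectional GRU sequence classifier with a temporal
  mean-pool head, trained with softmax cross-entropy and Adam. Forward
  pass, backpropagation through time and the optimizer are implemented in
  NumPy, so everything runs on one CPU. Transfer learning follows the
  head-surgery recipe: pretrain a binary murmur detector, clear the final
  layer, attach a zero-initialized 5-class head, fine-tune the whole
  network with patient-level 5-fold cross-validation and early stopping,
  and ensemble the fold models by averaging their softmax outputs.
- **Protocol** — Pocock–Simon covariate minimization for 50/50
  train/test splits balancing recruitment site, disease group, heart rate,
  maximum murmur intensity, body condition score and body weight; a
  repeated nested evaluation (fresh split per repeat, test arm never seen
  in training); patient-level percentile bootstrap CIs; vertically
  averaged ROC curves.
- **Clinical rules** — Levine→reduced grade conversion, LVIDDN, ACVIM
  echo staging, preclinical sample construction with its clean/confounded
  partition, and B1-vs-B2 classification from the model's left-apex
  probability of a loud-or-greater murmur, `P(loud) + P(thrilling)`.

## Worked example

`examples/03_train_and_grade.py` pretrains the base model, fine-tunes on
half of a 60-dog synthetic cohort and grades the held-out half:

```text
pretrained binary base model (surrogate for the human-data model)
held-out recordings graded:    90
exact-match grading accuracy:  0.90
within-one-grade agreement:    1.00
binary murmur-detection AUC:   1.000
```

90 recordings (3 auscultation sites × 30 held-out dogs) are graded; 90%
receive exactly the grade used to synthesize them, every prediction is
within one grade, and murmur-vs-no-murmur detection is perfect at this
signal-to-noise ratio. `examples/01…06` walk through each capability —
synthesis, cohort tables, training, splitting, staging rules and the full
pipeline; each prints its numbers with a line on what they mean.

A command-line surface wraps the same library calls:

```bash
caninepcg synth --n 100 --seed 1 --out data/
caninepcg split --cohort data/cohort.csv --seed 1 --out split.csv
caninepcg run --config config.yaml --out runs/demo
```

## Layout

```
src/caninepcg/   synth, features, model, split, evaluate, staging, io,
                 pipeline, cli
examples/        one narrative script per capability
tests/           unit, property and end-to-end acceptance tests
docs/methods.md  the model, its assumptions and design choices
```
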