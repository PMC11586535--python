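"""Transfer-learn the grading network on a small synthetic cohort.

Pretrains the binary-head base model on easy murmur/no-murmur recordings,
clears its final layer for the 5-grade head, fine-tunes with patient-level
5-fold cross-validation on half of a 60-dog cohort, and grades the held-out
half.  Takes a couple of minutes on one CPU.
"""

import numpy as np

from caninepcg import ModelConfig, RunConfig, finetune_crossval, \
    minimization_split, synthesize_cohort, transfer_head_surgery
from caninepcg.evaluate import grading_metrics, recordings_to_arrays, roc_curve
from caninepcg.grades import GRADES
from caninepcg.pipeline import pretrain_base

cfg = RunConfig(seed=3, pretrain_recordings=60,
                model=ModelConfig(hidden_size=32, max_epochs=25,
                                  learning_rate=0.01,
                                  early_stopping_patience=6))
base, _ = pretrain_base(cfg)
print("pretrained binary base model (surrogate for the human-data model)")

cohort, recordings = synthesize_cohort(60, seed=42)
X, y, pids, sites = recordings_to_arrays(cohort, recordings, cfg.features)
split = minimization_split(cohort, seed=1)
train = np.array([split.arm[p] == "train" for p in pids])

model = transfer_head_surgery(base, 5)
model.config = cfg.model
ens = finetune_crossval(model, X[train], y[train],
                        [p for p, t in zip(pids, train) if t], k=5, seed=2)
probs = ens.predict_proba(X[~train])
pred = probs.argmax(axis=1)

m = grading_metrics([GRADES[i] for i in pred], [GRADES[i] for i in y[~train]])
_, _, _, auc = roc_curve(1 - probs[:, 0], (y[~train] != 0).astype(int))
print(f"held-out recordings graded:    {int((~train).sum())}")
print(f"exact-match grading accuracy:  {m['accuracy']:.2f}")
print(f"within-one-grade agreement:    {m['within_one']:.2f}")
print(f"binary murmur-detection AUC:   {auc:.3f}")
print("\nThe ensemble of 5 fold models grades unseen dogs' recordings; most"
      "\nerrors are one grade, mirroring how experts disagree with each other.")
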