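"""Covariate-balanced 50/50 splitting versus simple randomization.

Splits a 300-dog synthetic cohort by Pocock-Simon minimization over the six
balancing variables and compares the residual per-variable imbalance with a
plain random half-split.
"""

import numpy as np

from caninepcg import minimization_split, synthesize_cohort
from caninepcg.split import extract_strata, imbalance_report

cohort, _ = synthesize_cohort(300, seed=11, audio=False)
strata = extract_strata(cohort)
ids = [r.patient_id for r in cohort]

assignment = minimization_split(cohort, seed=0)
print("minimized split per-variable |train - test| imbalance:")
for var, score in assignment.imbalance_report.items():
    print(f"  {var:<22} {score}")

rng = np.random.default_rng(0)
perm = rng.permutation(len(ids))
arm = {ids[i]: ("train" if k < len(ids) // 2 else "test")
       for k, i in enumerate(perm)}
rand = imbalance_report(arm, strata)
print(f"\ntotal imbalance, minimized:  {sum(assignment.imbalance_report.values())}")
print(f"total imbalance, random:     {sum(rand.values())}")
print("\nMinimization drives every stratum's count difference toward zero, so"
      "\nrepeated evaluations compare models on comparable halves.")
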