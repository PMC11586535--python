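"""ACVIM staging rules and the B1-versus-B2 decision layer.

Shows the echocardiographic staging thresholds (LA/Ao >= 1.6 and
LVIDDN >= 1.7 for B2), the preclinical sample construction with its
clean/confounded partition, and how a predicted grade distribution at the
left apex is turned into a stage call.
"""

import numpy as np

from caninepcg import (GradeDistribution, classify_b1_b2, compute_lviddn,
                       expert_rule_b1_b2, partition_preclinical, stage_mmvd,
                       synthesize_cohort)

print(f"LVIDDN for LVIDD 3.0 cm at 9.8 kg: {compute_lviddn(3.0, 9.8):.3f}")

cohort, _ = synthesize_cohort(500, seed=17, audio=False)
stages = [stage_mmvd(r) for r in cohort if r.disease == "MMVD"]
print(f"MMVD dogs staged from echo: B1={stages.count('B1')}, "
      f"B2={stages.count('B2')}, C={stages.count('C')}, D={stages.count('D')}")

part = partition_preclinical(cohort)
print(f"preclinical sample: clean={len(part.ids('clean'))}, "
      f"confounded={len(part.ids('confounded'))}, "
      f"excluded={len(part.ids('excluded'))}")

dist = GradeDistribution(np.array([0.02, 0.08, 0.20, 0.55, 0.15]))
call, score = classify_b1_b2(dist, threshold=0.5)
print(f"\nmodel left-apex distribution -> P(loud or thrilling) = {score:.2f}"
      f" -> stage {call}")
print(f"expert rule for an annotated 'loud' murmur -> "
      f"{expert_rule_b1_b2('loud')}")
print("\nThe continuous score lets the stage threshold trade sensitivity for"
      "\nspecificity; the expert rule is its binarized comparator.")
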