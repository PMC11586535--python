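"""ACVIM MMVD staging rules and the preclinical B1-vs-B2 classifier.

Stages: A (at-risk: normal heart, <15 kg), B1 (murmur without
echocardiographic remodeling), B2 (LA/Ao >= 1.6 and LVIDDN >= 1.7, both
inclusive), C/D (congestive heart failure, an input label assigned
clinically rather than computed here).  The preclinical analysis sample
keeps B1/B2 dogs only, excluding normal hearts, other diseases, C/D and
dogs on loop diuretics, and flags extremes of weight or age and pimobendan
use as a "confounded" subsample.

The machine-staging layer scores each dog by the model's predicted
probability of a loud-or-greater left-apex murmur, P(loud) + P(thrilling),
and calls B2 above a configurable threshold; the expert comparator stages
B2 whenever the annotated left-apex grade is loud or thrilling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grades import grade_index, reduce_levine  # noqa: F401  (re-exported)
from .model import GradeDistribution, loud_or_greater_probability
from .synth import CohortRecord


def compute_lviddn(lvidd: float, weight: float) -> float:
    """Body-weight-normalized LVIDD: lvidd (cm) / weight (kg) ** 0.294."""
    if lvidd <= 0 or weight <= 0:
        raise ValueError("lvidd and weight must be positive")
    return lvidd / weight ** 0.294


@dataclass(frozen=True)
class EchoMeasures:
    la_ao: float
    lvidd: float
    body_weight: float

    def __post_init__(self):
        if min(self.la_ao, self.lvidd, self.body_weight) <= 0:
            raise ValueError("echo measures must be positive")

    @property
    def lviddn(self) -> float:
        return compute_lviddn(self.lvidd, self.body_weight)


def meets_b2_echo_criteria(la_ao: float, lviddn: float) -> bool:
    """Inclusive echocardiographic remodeling thresholds for stage B2."""
    return la_ao >= 1.6 and lviddn >= 1.7


def stage_mmvd(record: CohortRecord) -> str:
    """Assign the ACVIM stage from diagnosis, weight and echo measures.

    C/D labels pass through from the input (heart-failure status is a
    clinical call).  Normal hearts under 15 kg are stage A; heavier normal
    dogs and non-MMVD diseases get "none".
    """
    if record.disease == "normal":
        return "A" if record.body_weight < 15 else "none"
    if record.disease != "MMVD":
        return "none"
    if record.mmvd_stage in ("C", "D"):
        return record.mmvd_stage
    import math
    if not (math.isfinite(record.la_ao) and math.isfinite(record.lvidd)):
        raise ValueError(f"missing echo values for MMVD dog {record.patient_id}")
    return "B2" if meets_b2_echo_criteria(record.la_ao, record.lviddn) else "B1"


@dataclass
class PreclinicalPartition:
    assignment: dict                       # patient_id -> clean|confounded|excluded
    exclusion_reason: dict = field(default_factory=dict)
    confounder_reason: dict = field(default_factory=dict)

    def ids(self, which: str) -> list:
        return [p for p, a in self.assignment.items() if a == which]


def partition_preclinical(cohort: list) -> PreclinicalPartition:
    """Build the preclinical MMVD sample and its clean/confounded split.

    Excluded: non-MMVD dogs, C/D (heart failure) and dogs on loop
    diuretics.  Remaining B1/B2 dogs are "confounded" when body weight is
    outside 2-25 kg, age is under 6 years, or the dog is on pimobendan;
    otherwise "clean".
    """
    assignment, excl, conf = {}, {}, {}
    for r in cohort:
        stage = r.mmvd_stage if r.mmvd_stage != "none" else stage_mmvd(r)
        if r.disease != "MMVD":
            assignment[r.patient_id] = "excluded"
            excl[r.patient_id] = "not_mmvd"
        elif stage in ("C", "D"):
            assignment[r.patient_id] = "excluded"
            excl[r.patient_id] = "heart_failure"
        elif r.loop_diuretic_flag:
            assignment[r.patient_id] = "excluded"
            excl[r.patient_id] = "loop_diuretic"
        else:
            reasons = []
            if r.body_weight < 2 or r.body_weight > 25:
                reasons.append("weight_outside_2_25kg")
            if r.age < 6:
                reasons.append("age_lt_6y")
            if r.pimobendan_flag:
                reasons.append("pimobendan")
            if reasons:
                assignment[r.patient_id] = "confounded"
                conf[r.patient_id] = reasons
            else:
                assignment[r.patient_id] = "clean"
    return PreclinicalPartition(assignment=assignment, exclusion_reason=excl,
                                confounder_reason=conf)


def classify_b1_b2(left_apex_dist: GradeDistribution,
                   threshold: float = 0.5) -> tuple[str, float]:
    """Stage from the model's left-apex grade distribution.

    The continuous score is P(loud) + P(thrilling); the dog is called B2
    when the score reaches ``threshold``.  The default 0.5 corresponds to
    the specific operating point where a predicted loud-or-thrilling
    murmur decides B2.
    """
    score = loud_or_greater_probability(left_apex_dist)
    return ("B2" if score >= threshold else "B1"), score


def expert_rule_b1_b2(left_apex_reduced_grade: str) -> str:
    """Expert comparator: B2 iff the annotated grade is loud or thrilling."""
    return "B2" if grade_index(left_apex_reduced_grade) >= grade_index("loud") \
        else "B1"
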