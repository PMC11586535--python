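"""Covariate-balanced 50/50 cohort splitting by Pocock-Simon minimization.

Patients are processed in a seeded random order.  Each patient is assigned
to the arm (train or test) that minimizes the summed marginal imbalance of
six balancing variables: recruitment site, disease group (MMVD / normal /
other), heart rate, maximum murmur intensity, body condition score and body
weight.  Continuous variables are binned (heart rate and weight into
cohort terciles; BCS as <5 vs >=5); missing values form their own stratum.
Total arm size acts as a dominant-weight balancing term, so arm sizes never
differ by more than one.  Ties are broken by a seeded coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import CohortRecord

DEFAULT_VARIABLES = ("recruitment_site", "disease_group", "heart_rate",
                     "max_murmur_intensity", "bcs", "body_weight")

_MISSING = "<missing>"


@dataclass
class SplitAssignment:
    arm: dict                                  # patient_id -> "train" | "test"
    imbalance_report: dict = field(default_factory=dict)
    seed: int = 0

    def patients(self, which: str) -> list:
        return [p for p, a in self.arm.items() if a == which]


def _disease_group(record: CohortRecord) -> str:
    if record.disease in ("MMVD", "normal"):
        return record.disease
    return "other"


def _tercile_edges(values: list) -> np.ndarray:
    arr = np.array([v for v in values if v is not None and np.isfinite(v)])
    if arr.size == 0:
        return np.array([])
    return np.quantile(arr, [1 / 3, 2 / 3])


def _bin_value(value, edges) -> str:
    if value is None or not np.isfinite(value):
        return _MISSING
    return f"bin{int(np.searchsorted(edges, value, side='right'))}"


def extract_strata(cohort: list, variables=DEFAULT_VARIABLES) -> dict:
    """Per-patient stratum label for each balancing variable."""
    known = set(DEFAULT_VARIABLES)
    for v in variables:
        if v not in known:
            raise ValueError(f"unknown balancing variable {v!r}; known: "
                             f"{sorted(known)}")
    hr_edges = _tercile_edges([r.heart_rate for r in cohort])
    bw_edges = _tercile_edges([r.body_weight for r in cohort])
    strata: dict = {}
    for r in cohort:
        s = {}
        for v in variables:
            if v == "recruitment_site":
                s[v] = r.site_of_recruitment
            elif v == "disease_group":
                s[v] = _disease_group(r)
            elif v == "heart_rate":
                s[v] = _bin_value(r.heart_rate, hr_edges)
            elif v == "max_murmur_intensity":
                s[v] = r.max_reduced_grade
            elif v == "bcs":
                s[v] = _MISSING if r.bcs is None else ("lt5" if r.bcs < 5 else "ge5")
            elif v == "body_weight":
                s[v] = _bin_value(r.body_weight, bw_edges)
        strata[r.patient_id] = s
    return strata


def assign_sequential(ordered_ids: list, strata: dict, rng) -> dict:
    """Online minimization over a fixed processing order.

    Assigning further patients never changes earlier assignments.  When arm
    totals differ the patient joins the smaller arm (dominant size term);
    at equal totals the arm minimizing summed per-variable marginal
    imbalance wins, with seeded coin-flip tie-breaks.
    """
    counts: dict = {}          # (variable, stratum) -> {"train": n, "test": n}
    totals = {"train": 0, "test": 0}
    arm: dict = {}
    for pid in ordered_ids:
        s = strata[pid]
        if totals["train"] != totals["test"]:
            choice = "train" if totals["train"] < totals["test"] else "test"
        else:
            scores = {}
            for cand in ("train", "test"):
                score = 0
                for v, lab in s.items():
                    c = counts.get((v, lab), {"train": 0, "test": 0})
                    ctr = dict(c)
                    ctr[cand] += 1
                    score += abs(ctr["train"] - ctr["test"])
                scores[cand] = score
            if scores["train"] < scores["test"]:
                choice = "train"
            elif scores["test"] < scores["train"]:
                choice = "test"
            else:
                choice = "train" if rng.random() < 0.5 else "test"
        arm[pid] = choice
        totals[choice] += 1
        for v, lab in s.items():
            c = counts.setdefault((v, lab), {"train": 0, "test": 0})
            c[choice] += 1
    return arm


def _refine_by_swaps(arm: dict, strata: dict, max_passes: int = 20) -> dict:
    """Deterministic first-improvement swap polish at fixed arm sizes.

    The sequential pass is greedy and order effects can leave avoidable
    imbalance (e.g. both members of an identical covariate pair in one
    arm); exchanging one train patient with one test patient whenever it
    lowers the summed marginal imbalance removes it.
    """
    counts: dict = {}
    for pid, a in arm.items():
        for v, lab in strata[pid].items():
            c = counts.setdefault((v, lab), {"train": 0, "test": 0})
            c[a] += 1

    def _delta(pid, frm, to):
        d = 0
        for v, lab in strata[pid].items():
            c = counts[(v, lab)]
            before = abs(c["train"] - c["test"])
            sign = 1 if frm == "train" else -1
            after = abs((c["train"] - c["test"]) - 2 * sign)
            d += after - before
        return d

    arm = dict(arm)
    order = sorted(arm)
    for _ in range(max_passes):
        improved = False
        train_ids = [p for p in order if arm[p] == "train"]
        test_ids = [p for p in order if arm[p] == "test"]
        for t in train_ids:
            for u in test_ids:
                if arm[t] != "train" or arm[u] != "test":
                    continue
                dt = _delta(t, "train", "test")
                # apply t's move provisionally to evaluate u's
                for v, lab in strata[t].items():
                    counts[(v, lab)]["train"] -= 1
                    counts[(v, lab)]["test"] += 1
                du = _delta(u, "test", "train")
                if dt + du < 0:
                    for v, lab in strata[u].items():
                        counts[(v, lab)]["test"] -= 1
                        counts[(v, lab)]["train"] += 1
                    arm[t], arm[u] = "test", "train"
                    improved = True
                else:
                    for v, lab in strata[t].items():
                        counts[(v, lab)]["train"] += 1
                        counts[(v, lab)]["test"] -= 1
        if not improved:
            break
    return arm


def minimization_split(cohort: list, variables=DEFAULT_VARIABLES,
                       ratio: float = 0.5, seed: int = 0,
                       refine: bool = True) -> SplitAssignment:
    """Split a cohort into balanced train/test halves.

    Runs the online sequential minimization over a seeded random patient
    order, then (by default) a deterministic swap-refinement pass that
    keeps arm sizes fixed while removing residual order-induced imbalance.
    Only a 50/50 ratio is supported (the evaluation protocol's split);
    ``ratio`` is validated to document the contract.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if abs(ratio - 0.5) > 1e-9:
        raise ValueError("only ratio=0.5 is supported")
    strata = extract_strata(cohort, variables)
    rng = np.random.default_rng(seed)
    order = [cohort[i].patient_id for i in rng.permutation(len(cohort))]
    arm = assign_sequential(order, strata, rng)
    if refine:
        arm = _refine_by_swaps(arm, strata)
    report = imbalance_report(arm, strata)
    return SplitAssignment(arm=arm, imbalance_report=report, seed=seed)


def imbalance_report(arm: dict, strata: dict) -> dict:
    """Final |train - test| count per variable, summed over strata."""
    out: dict = {}
    for pid, a in arm.items():
        for v, lab in strata[pid].items():
            c = out.setdefault(v, {}).setdefault(lab, {"train": 0, "test": 0})
            c[a] += 1
    return {v: sum(abs(c["train"] - c["test"]) for c in labs.values())
            for v, labs in out.items()}
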