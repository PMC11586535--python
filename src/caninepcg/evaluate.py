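"""Repeated-split evaluation protocol, bootstrap CIs and ROC machinery.

The evaluation mirrors a nested repeated-stratification design: the cohort
is split 50/50 by covariate minimization, the pretrained base model gets a
fresh 5-class head, is fine-tuned with patient-level 5-fold
cross-validation on the training arm, and predicts only the held-out test
arm.  The whole procedure repeats with fresh split seeds (50 by default),
so each patient is scored in roughly half the repeats.  Uncertainty comes
from patient-level bootstrap resampling (1000 draws by default) pooled
across repeats; ROC curves are combined by vertical averaging on a fixed
false-positive-rate grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from . import tables
from .grades import GRADES, N_GRADES, grade_index
from .model import (Ensemble, GradeDistribution, GRUModel, aggregate_patient,
                    binary_murmur_probability, finetune_crossval,
                    spectrogram_batch, transfer_head_surgery)
from .split import minimization_split
from .synth import CohortRecord, Recording
from .tables import PublishedTableFixture


@dataclass(frozen=True)
class EvaluationConfig:
    n_repeats: int = 50
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1 or self.n_bootstrap < 1:
            raise ValueError("n_repeats and n_bootstrap must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class EvaluationRun:
    repeat_index: int
    seed: int
    split: object                      # SplitAssignment
    predictions: pd.DataFrame          # one row per scored test-arm recording
    train_recording_ids: set = field(default_factory=set)


@dataclass
class ROCSummary:
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_low: np.ndarray
    tpr_high: np.ndarray
    auc_mean: float
    auc_ci: tuple


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


# --------------------------------------------------------------------------
# ROC


def roc_curve(scores, labels):
    """Empirical ROC (FPR, TPR, thresholds) and trapezoid AUC.

    Tied scores collapse into single ROC vertices, so the trapezoid AUC
    equals the pair-counting statistic with ties scored 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = set(np.unique(labels))
    if classes != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    return fpr, tpr, thr, float(skm.auc(fpr, tpr))


def vertical_average(curves: list, fpr_grid=None,
                     ci_level: float = 0.95) -> ROCSummary:
    """Average ROC curves vertically: mean/percentile TPR at fixed FPRs.

    Each curve is a (fpr, tpr) pair; linear interpolation onto a common
    grid (101 points by default).  AUC summaries come from the per-curve
    trapezoid AUCs.
    """
    if not curves:
        raise ValueError("need at least one ROC curve")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    interp, aucs = [], []
    for fpr, tpr in curves:
        interp.append(np.interp(fpr_grid, fpr, tpr))
        aucs.append(np.trapezoid(tpr, fpr))
    interp = np.array(interp)
    alpha = (1 - ci_level) / 2
    return ROCSummary(
        fpr_grid=np.asarray(fpr_grid),
        tpr_mean=interp.mean(axis=0),
        tpr_low=np.quantile(interp, alpha, axis=0),
        tpr_high=np.quantile(interp, 1 - alpha, axis=0),
        auc_mean=float(np.mean(aucs)),
        auc_ci=(float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha))),
    )


def select_operating_point(scores, labels, mode: str = "sensitive",
                           target: float = 0.85) -> OperatingPoint:
    """Pick a threshold from pooled scores.

    ``sensitive``: maximize specificity subject to sensitivity >= target;
    ``specific``: maximize sensitivity subject to specificity >= target.
    """
    fpr, tpr, thr, _ = roc_curve(scores, labels)
    spec = 1 - fpr
    if mode == "sensitive":
        ok = tpr >= target
        if not ok.any():
            ok = tpr >= tpr.max()
        i = np.argmax(np.where(ok, spec, -1))
    elif mode == "specific":
        ok = spec >= target
        if not ok.any():
            ok = spec >= spec.max()
        i = np.argmax(np.where(ok, tpr, -1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OperatingPoint(threshold=float(thr[i]), sensitivity=float(tpr[i]),
                          specificity=float(spec[i]))


# --------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    mean: float
    ci: tuple
    draws: np.ndarray


def bootstrap_ci(runs: list, statistic, n_bootstrap: int = 1000,
                 ci_level: float = 0.95, seed: int = 0,
                 max_redraws: int = 100) -> BootstrapResult:
    """Patient-level percentile bootstrap pooled across runs.

    ``runs`` is a list of runs; each run is a dict patient_id -> per-patient
    data (any object the ``statistic`` understands).  For each bootstrap
    iteration, patients are resampled with replacement within each run and
    ``statistic`` is applied to the resampled data list.  Draws for which
    the statistic is undefined (returns NaN) are redrawn.
    """
    if not runs:
        raise ValueError("no runs to bootstrap")
    rng = np.random.default_rng(seed)
    draws = []
    for run in runs:
        pids = list(run)
        if not pids:
            raise ValueError("empty run")
        for _ in range(n_bootstrap):
            val = math.nan
            for _attempt in range(max_redraws):
                take = rng.integers(0, len(pids), size=len(pids))
                data = [run[pids[i]] for i in take]
                val = float(statistic(data))
                if not math.isnan(val):
                    break
            draws.append(val)
    draws = np.array(draws)
    alpha = (1 - ci_level) / 2
    return BootstrapResult(mean=float(draws.mean()),
                           ci=(float(np.quantile(draws, alpha)),
                               float(np.quantile(draws, 1 - alpha))),
                           draws=draws)


# --------------------------------------------------------------------------
# grading metrics


def grading_metrics(predicted, expert) -> dict:
    """Micro-averaged accuracy, within-one-grade rate and confusion matrix.

    The confusion matrix follows the published layout: rows are algorithm
    predictions, columns expert grades, each non-empty column normalized to
    sum to 1.
    """
    p = np.array([grade_index(g) for g in predicted])
    e = np.array([grade_index(g) for g in expert])
    if p.shape != e.shape:
        raise ValueError("prediction and expert label vectors differ in length")
    if p.size == 0:
        raise ValueError("empty label vectors")
    acc = float(np.mean(p == e))
    within1 = float(np.mean(np.abs(p - e) <= 1))
    conf = np.zeros((N_GRADES, N_GRADES))
    for pi, ei in zip(p, e):
        conf[pi, ei] += 1
    col = conf.sum(axis=0, keepdims=True)
    norm = np.divide(conf, col, out=np.zeros_like(conf), where=col > 0)
    return {"accuracy": acc, "within_one": within1,
            "confusion": norm, "counts": conf}


def sensitivity_by_group(patient_predictions: dict, groups: dict,
                         n_bootstrap: int = 1000, ci_level: float = 0.95,
                         seed: int = 0) -> dict:
    """Per-group murmur-detection sensitivity with bootstrap CIs.

    ``patient_predictions`` maps patient_id -> PatientPrediction; ``groups``
    maps patient_id -> group label (e.g. disease).  Also reports, per group,
    how often each site belongs to the maximal-predicted-grade set (shared
    maxima count for every site involved).
    """
    out = {}
    rng_seed = seed
    for g in sorted(set(groups.values())):
        pids = [p for p, gg in groups.items() if gg == g and p in patient_predictions]
        if not pids:
            raise ValueError(f"empty group {g!r}")
        flags = {p: float(patient_predictions[p].murmur_flag) for p in pids}
        bs = bootstrap_ci([flags], lambda vals: float(np.mean(vals)),
                          n_bootstrap=n_bootstrap, ci_level=ci_level,
                          seed=rng_seed)
        site_rates = {}
        for site in ("left_apex", "left_base", "right_side"):
            hits = [p for p in pids
                    if site in patient_predictions[p].sites_of_maximal_predicted_grade]
            flagged = [p for p in pids if patient_predictions[p].murmur_flag]
            site_rates[site] = len(hits) / len(flagged) if flagged else 0.0
        out[g] = {"n": len(pids), "sensitivity": float(np.mean(list(flags.values()))),
                  "ci": bs.ci, "maximal_site_rates": site_rates}
        rng_seed += 1
    return out


# --------------------------------------------------------------------------
# cohort summaries (printed-table reproduction)


def _pct(num: float, den: float) -> int:
    if den <= 0:
        raise ValueError("empty denominator")
    return int(math.floor(100.0 * num / den + 0.5))


class CohortSummary:
    """Cross-tabulations with integer percentages, from records or fixtures.

    For fixture input the printed counts are used directly (denominators
    are column totals, so multi-disease dogs counted in several columns
    behave as printed); for a list of records the tabulations are computed
    from the per-dog grades and stages.
    """

    def __init__(self, source):
        if isinstance(source, PublishedTableFixture):
            self._fixture = source
            self._records = None
        else:
            records = list(source)
            if not records:
                raise ValueError("empty cohort")
            self._fixture = None
            self._records = records

    # -- disease x max grade (table2 semantics) --------------------------

    def grade_counts(self, disease: str) -> dict:
        if self._fixture is not None:
            if self._fixture.table_id != "table2":
                raise ValueError("disease tabulations need the table2 fixture")
            return dict(self._fixture.counts["max_intensity"][disease])
        counts = {g: 0 for g in GRADES}
        for r in self._records:
            if r.disease == disease:
                counts[r.max_reduced_grade] += 1
        return counts

    def percent_any_murmur(self, disease: str) -> int:
        c = self.grade_counts(disease)
        total = sum(c.values())
        return _pct(total - c["none"], total)

    def percent_grade(self, disease: str, grade: str) -> int:
        c = self.grade_counts(disease)
        return _pct(c[grade], sum(c.values()))

    def percent_point_of_max(self, disease: str, site: str) -> int:
        if self._fixture is not None:
            pom = self._fixture.counts["point_of_max"][disease]
            # printed denominators are the intensity column totals
            den = sum(self._fixture.counts["max_intensity"][disease].values())
            return _pct(pom[site], den)
        pids = [r for r in self._records if r.disease == disease]
        hits = sum(1 for r in pids if r.point_of_maximal_intensity == site)
        return _pct(hits, len(pids))

    # -- stage x left-apex grade (table3 semantics) ----------------------

    def stage_apex_counts(self, stage: str) -> dict:
        if self._fixture is not None:
            if self._fixture.table_id != "table3":
                raise ValueError("stage tabulations need the table3 fixture")
            return dict(self._fixture.counts["left_apex_grade"][stage])
        counts = {g: 0 for g in GRADES}
        for r in self._records:
            st = "C/D" if r.mmvd_stage in ("C", "D") else r.mmvd_stage
            if st == stage:
                counts[r.reduced_grade("left_apex")] += 1
        return counts

    def percent_loud_or_thrilling_at_apex(self, stage: str) -> int:
        c = self.stage_apex_counts(stage)
        if self._fixture is not None:
            den = self._fixture.count("n", stage)
        else:
            den = sum(c.values())
        return _pct(c["loud"] + c["thrilling"], den)


def cohort_summary(source) -> CohortSummary:
    """Cross-tabulation view over a cohort or a printed-table fixture."""
    return CohortSummary(source)


# --------------------------------------------------------------------------
# nested repeated evaluation


def recordings_to_arrays(cohort: list, recordings: list, spectrogram=None):
    """Features, labels and bookkeeping arrays for the full recording set."""
    by_pid = {r.patient_id: r for r in cohort}
    X = spectrogram_batch(recordings, spectrogram) if spectrogram \
        else spectrogram_batch(recordings)
    y = np.array([grade_index(by_pid[rec.patient_id].reduced_grade(rec.site))
                  for rec in recordings])
    pids = [rec.patient_id for rec in recordings]
    sites = [rec.site for rec in recordings]
    return X, y, pids, sites


def nested_repeated_evaluation(cohort: list, recordings: list,
                               eval_config: EvaluationConfig,
                               pretrained_base: GRUModel,
                               features=None) -> list:
    """Run the repeated split -> head surgery -> fine-tune -> test protocol.

    ``features`` may carry precomputed ``(X, y, pids, sites)`` to avoid
    recomputing spectrograms across repeats.  Each repeat scores only the
    test arm; the returned runs carry the per-recording grade probabilities
    and the train-set recording ids for leakage auditing.
    """
    if features is None:
        features = recordings_to_arrays(cohort, recordings,
                                        pretrained_base.spectrogram)
    X, y, pids, sites = features
    rec_index = np.arange(len(pids))
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(eval_config.seed)
             .spawn(eval_config.n_repeats)]
    runs = []
    for rep, rep_seed in enumerate(seeds):
        split = minimization_split(cohort, seed=rep_seed)
        train_mask = np.array([split.arm[p] == "train" for p in pids])
        model = transfer_head_surgery(pretrained_base, N_GRADES)
        ensemble = finetune_crossval(
            model, X[train_mask], y[train_mask],
            [p for p, m in zip(pids, train_mask) if m],
            k=eval_config.k_folds, seed=rep_seed)
        test_idx = rec_index[~train_mask]
        probs = ensemble.predict_proba(X[test_idx])
        rows = []
        for j, i in enumerate(test_idx):
            row = {"patient_id": pids[i], "site": sites[i],
                   "expert_grade": GRADES[y[i]],
                   "predicted_grade": GRADES[int(np.argmax(probs[j]))],
                   "arm": "test"}
            for gi, g in enumerate(GRADES):
                row[f"p_{g}"] = float(probs[j, gi])
            rows.append(row)
        runs.append(EvaluationRun(
            repeat_index=rep, seed=rep_seed, split=split,
            predictions=pd.DataFrame(rows),
            train_recording_ids={(pids[i], sites[i])
                                 for i in rec_index[train_mask]}))
    return runs


def count_test_memberships(runs: list, cohort: list) -> dict:
    """How many repeats each patient spent in the test arm."""
    counts = {r.patient_id: 0 for r in cohort}
    for run in runs:
        for pid, arm in run.split.arm.items():
            if arm == "test":
                counts[pid] += 1
    return counts
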