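"""End-to-end workflow: synthesize -> pretrain -> evaluate -> stage.

A single ``RunConfig`` (loadable from YAML) drives the full pipeline.  One
global seed deterministically derives per-stage seeds by hashing the stage
name, so stages are independent yet the whole run reproduces bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .evaluate import (EvaluationConfig, bootstrap_ci, cohort_summary,
                       grading_metrics, nested_repeated_evaluation,
                       recordings_to_arrays, roc_curve, vertical_average)
from .features import MODEL_SPECTROGRAM, SpectrogramConfig
from .grades import GRADES, grade_index
from .model import (GradeDistribution, ModelConfig, build_base_model,
                    binary_murmur_probability, loud_or_greater_probability,
                    surrogate_pretrain, transfer_head_surgery)
from .staging import partition_preclinical
from .synth import SynthesisConfig, synthesize_cohort, synthesize_pcg


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of stage name mixed with the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _build(cls, section: dict, location: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section "
                         f"{location!r}")
    return cls(**section)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_dogs: int = 60
    pretrain_recordings: int = 120
    staging_threshold: float = 0.5
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    features: SpectrogramConfig = field(default_factory=lambda: MODEL_SPECTROGRAM)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self):
        if self.n_dogs <= 0:
            raise ValueError("n_dogs must be positive")
        if self.pretrain_recordings < 4:
            raise ValueError("pretrain_recordings must be at least 4")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {"synthesis": SynthesisConfig, "features": SpectrogramConfig,
                    "model": ModelConfig, "evaluation": EvaluationConfig}
        kwargs = {}
        for name, klass in sections.items():
            if name in d:
                sec = d.pop(name)
                if name == "features" and "frequency_range" in sec:
                    sec["frequency_range"] = tuple(sec["frequency_range"])
                kwargs[name] = _build(klass, sec, name)
        scalars = {"seed", "n_dogs", "pretrain_recordings", "staging_threshold"}
        unknown = set(d) - scalars
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_pretrain_set(n: int, seed: int, features: SpectrogramConfig,
                      noise_rms: float = 0.01):
    """Easy binary pretraining set: half silent-murmur, half loud, low noise."""
    from .model import spectrogram_batch
    recs, labels = [], []
    rng = np.random.default_rng(seed)
    for i in range(n):
        grade = "none" if i % 2 == 0 else "loud"
        cfg = SynthesisConfig(heart_rate=float(rng.uniform(80, 160)),
                              murmur_grade=grade,
                              ambient_noise_rms=noise_rms,
                              seed=int(rng.integers(2**31)))
        recs.append(synthesize_pcg(cfg, patient_id=f"pre{i:04d}"))
        labels.append(0 if grade == "none" else 1)
    return spectrogram_batch(recs, features), np.array(labels)


def pretrain_base(config: RunConfig):
    """Build and surrogate-pretrain the binary-head base model."""
    model_cfg = dataclasses.replace(config.model, num_output_classes=2,
                                    seed=derive_seed(config.seed, "base_init"))
    base = build_base_model(model_cfg, spectrogram=config.features)
    X, y = make_pretrain_set(config.pretrain_recordings,
                             derive_seed(config.seed, "pretrain_data"),
                             config.features)
    hist = surrogate_pretrain(base, X, y, seed=derive_seed(config.seed, "pretrain"))
    return base, hist


def _binary_roc_per_run(runs):
    curves = []
    for run in runs:
        df = run.predictions
        scores = 1.0 - df["p_none"].to_numpy()
        labels = (df["expert_grade"] != "none").astype(int).to_numpy()
        if labels.min() == labels.max():
            continue
        fpr, tpr, _, _ = roc_curve(scores, labels)
        curves.append((fpr, tpr))
    return curves


def _staging_scores(runs, cohort):
    """Mean left-apex loud-or-greater score per preclinical dog, + B2 labels."""
    part = partition_preclinical(cohort)
    keep = set(part.ids("clean")) | set(part.ids("confounded"))
    stage = {r.patient_id: r.mmvd_stage for r in cohort}
    acc: dict = {}
    for run in runs:
        df = run.predictions
        apex = df[df["site"] == "left_apex"]
        for _, row in apex.iterrows():
            pid = row["patient_id"]
            if pid in keep:
                acc.setdefault(pid, []).append(row["p_loud"] + row["p_thrilling"])
    pids = sorted(acc)
    scores = np.array([np.mean(acc[p]) for p in pids])
    labels = np.array([1 if stage[p] == "B2" else 0 for p in pids])
    return pids, scores, labels, part


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full workflow and write artifacts to ``out_dir``.

    Writes the cohort manifest, pooled per-repeat predictions, ROC summary
    tables, a metrics JSON and a structured log.  Returns the metrics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage, **kv):
        line = f"stage={stage} " + " ".join(f"{k}={v}" for k, v in kv.items())
        log_lines.append(line)

    t0 = time.time()
    synth_seed = derive_seed(config.seed, "cohort")
    cohort, recordings = synthesize_cohort(config.n_dogs, seed=synth_seed,
                                           synthesis=config.synthesis)
    cio.write_cohort(cohort, out / "cohort.csv")
    log("synth", seed=synth_seed, n_dogs=len(cohort), n_recordings=len(recordings))

    base, hist = pretrain_base(config)
    log("pretrain", seed=derive_seed(config.seed, "pretrain"),
        epochs=len(hist.train_loss), converged=hist.converged)

    feats = recordings_to_arrays(cohort, recordings, config.features)
    eval_cfg = dataclasses.replace(config.evaluation,
                                   seed=derive_seed(config.seed, "evaluation"))
    runs = nested_repeated_evaluation(cohort, recordings, eval_cfg, base,
                                      features=feats)
    pooled = [run.predictions.assign(repeat=run.repeat_index) for run in runs]
    all_preds = pd.concat(pooled, ignore_index=True)
    all_preds.to_csv(out / "predictions.csv", index=False)
    log("evaluate", n_repeats=len(runs),
        n_predictions=len(all_preds))

    metrics: dict = {}
    curves = _binary_roc_per_run(runs)
    if curves:
        summ = vertical_average(curves, ci_level=eval_cfg.ci_level)
        metrics["binary_auc_mean"] = summ.auc_mean
        metrics["binary_auc_ci"] = list(summ.auc_ci)
        pd.DataFrame({"fpr": summ.fpr_grid, "tpr_mean": summ.tpr_mean,
                      "tpr_low": summ.tpr_low, "tpr_high": summ.tpr_high}) \
            .to_csv(out / "roc_binary.csv", index=False)

    gm = grading_metrics(all_preds["predicted_grade"], all_preds["expert_grade"])
    metrics["grading_accuracy"] = gm["accuracy"]
    metrics["grading_within_one"] = gm["within_one"]

    acc_runs = []
    for run in runs:
        per_patient: dict = {}
        for _, row in run.predictions.iterrows():
            per_patient.setdefault(row["patient_id"], []).append(
                (row["predicted_grade"], row["expert_grade"]))
        acc_runs.append(per_patient)
    bs = bootstrap_ci(
        acc_runs,
        lambda items: float(np.mean([p == e for recs in items for p, e in recs])),
        n_bootstrap=eval_cfg.n_bootstrap, ci_level=eval_cfg.ci_level,
        seed=derive_seed(config.seed, "bootstrap"))
    metrics["grading_accuracy_ci"] = list(bs.ci)

    pids, scores, labels, part = _staging_scores(runs, cohort)
    if len(pids) and labels.min() != labels.max():
        fpr, tpr, _, auc = roc_curve(scores, labels)
        metrics["staging_auc"] = auc
        metrics["staging_n"] = int(len(pids))
        pd.DataFrame({"patient_id": pids, "score": scores, "is_b2": labels}) \
            .to_csv(out / "staging_scores.csv", index=False)
    log("staging", n_preclinical=len(pids),
        n_clean=len(part.ids("clean")), n_confounded=len(part.ids("confounded")),
        n_excluded=len(part.ids("excluded")))

    metrics["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
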