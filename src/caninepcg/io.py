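"""Cohort tables, WAV audio and model checkpoints on disk.

The cohort manifest is a CSV with one row per dog and a versioned schema:
required columns are enforced on read, unknown columns are preserved but
ignored, and blank or "NA" cells mark missing values (missingness is
first-class — clinical tables routinely have it).  Audio is mono 16-bit
PCM WAV.  Checkpoints bundle the parameter arrays with the model and
spectrogram configuration and a format version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import SpectrogramConfig
from .model import GRUModel, ModelConfig
from .synth import CohortRecord, Recording, SITES

SCHEMA_VERSION = 1

_REQUIRED = ["patient_id", "site_of_recruitment", "disease", "mmvd_stage",
             "age_years", "body_weight_kg", "bcs", "sex", "heart_rate_bpm",
             "arrhythmia", "levine_left_apex", "levine_left_base",
             "levine_right_side", "point_of_maximal_intensity", "la_ao",
             "lvidd_cm", "pimobendan", "loop_diuretic"]

_NA = ("", "NA", "nan", "NaN", "None")


def write_cohort(records: list, path) -> None:
    rows = []
    for r in records:
        rows.append({
            "schema_version": SCHEMA_VERSION,
            "patient_id": r.patient_id,
            "site_of_recruitment": r.site_of_recruitment,
            "disease": r.disease,
            "mmvd_stage": r.mmvd_stage,
            "age_years": r.age,
            "body_weight_kg": r.body_weight,
            "bcs": "" if r.bcs is None else r.bcs,
            "sex": r.sex,
            "heart_rate_bpm": r.heart_rate,
            "arrhythmia": int(r.arrhythmia_flag),
            "levine_left_apex": r.levine_grades.get("left_apex", 0),
            "levine_left_base": r.levine_grades.get("left_base", 0),
            "levine_right_side": r.levine_grades.get("right_side", 0),
            "point_of_maximal_intensity": r.point_of_maximal_intensity or "",
            "la_ao": r.la_ao,
            "lvidd_cm": r.lvidd,
            "pimobendan": int(r.pimobendan_flag),
            "loop_diuretic": int(r.loop_diuretic_flag),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _cell(row, col, kind, line_no):
    raw = row[col]
    if pd.isna(raw) or (isinstance(raw, str) and raw.strip() in _NA):
        return None
    try:
        return kind(raw)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable cell at row {line_no}, column {col!r}: "
                         f"{raw!r}")


def read_cohort(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required column(s): "
                         f"{missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2
        bcs = _cell(row, "bcs", lambda v: int(float(v)), line)
        la_ao = _cell(row, "la_ao", float, line)
        lvidd = _cell(row, "lvidd_cm", float, line)
        pmi = row["point_of_maximal_intensity"].strip() or None
        records.append(CohortRecord(
            patient_id=row["patient_id"],
            site_of_recruitment=row["site_of_recruitment"],
            disease=row["disease"],
            mmvd_stage=row["mmvd_stage"],
            age=_cell(row, "age_years", float, line),
            body_weight=_cell(row, "body_weight_kg", float, line),
            bcs=bcs,
            sex=row["sex"],
            heart_rate=_cell(row, "heart_rate_bpm", float, line),
            arrhythmia_flag=bool(_cell(row, "arrhythmia", lambda v: int(float(v)), line)),
            levine_grades={s: _cell(row, f"levine_{s}", lambda v: int(float(v)), line)
                           for s in SITES},
            point_of_maximal_intensity=pmi,
            la_ao=float("nan") if la_ao is None else la_ao,
            lvidd=float("nan") if lvidd is None else lvidd,
            pimobendan_flag=bool(_cell(row, "pimobendan", lambda v: int(float(v)), line)),
            loop_diuretic_flag=bool(_cell(row, "loop_diuretic",
                                          lambda v: int(float(v)), line)),
        ))
    return records


# --------------------------------------------------------------------------
# WAV


def write_wav(recording: Recording, path) -> None:
    """Write mono 16-bit PCM."""
    x = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), recording.sample_rate, pcm)


def read_wav(path, patient_id: str = "unknown", site: str = "left_apex") -> Recording:
    """Read a mono PCM WAV, normalizing amplitudes to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        x = data / 32767.0
    elif data.dtype == np.int32:
        x = data / 2147483647.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 127.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    x = np.clip(x, -1.0, 1.0)
    return Recording(patient_id=patient_id, site=site, samples=x, sample_rate=rate)


# --------------------------------------------------------------------------
# checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(model: GRUModel, path) -> None:
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "input_dim": model.input_dim,
        "config": dataclasses.asdict(model.config),
        "spectrogram": dataclasses.asdict(model.spectrogram),
    }
    np.savez(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path) -> GRUModel:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version "
                             f"{meta['format_version']}")
        spec = meta["spectrogram"]
        spec["frequency_range"] = tuple(spec["frequency_range"])
        model = GRUModel(ModelConfig(**meta["config"]), meta["input_dim"],
                         SpectrogramConfig(**spec))
        model.params = {k: z[k] for k in z.files if k != "__meta__"}
    return model
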