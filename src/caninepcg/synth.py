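"""Synthetic phonocardiograms and cohorts with controllable murmur grade.

The waveform model is deliberately minimal: each heartbeat contributes an S1
and an S2 transient (damped low-frequency sinusoids bounding systole), and a
murmur — when present — is band-limited Gaussian noise occupying systole (or
the whole cycle for a continuous shunt murmur).  Murmur loudness encodes the
reduced grade through its RMS relative to the S1/S2 transients, mirroring
the clinical definitions: soft murmurs are quieter than S1/S2, moderate
equal, loud louder, and thrilling murmurs are louder still with an added
low-frequency (<80 Hz) component standing in for the palpable thrill.

The cohort generator draws diagnoses, ACVIM stages, per-site Levine grades,
echocardiographic measures and medication flags whose marginal distributions
match the published cohort tables, then renders one waveform per
auscultation site at the grade implied by that site's Levine grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import tables
from .grades import GRADES, grade_index, reduce_levine

SITES = ("left_apex", "left_base", "right_side")

#: murmur RMS relative to the S1 transient RMS, per reduced grade
GRADE_RMS_RATIO = {"none": 0.0, "soft": 0.4, "moderate": 1.0,
                   "loud": 2.0, "thrilling": 2.5}

_SYSTOLE_FRACTION = 1 / 3  # fraction of the beat interval occupied by systole


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of a single synthetic phonocardiogram."""

    heart_rate: float = 120.0          # beats/min
    sample_rate: int = 4000            # Hz
    duration: float = 15.0             # seconds
    murmur_grade: str = "none"         # reduced scale
    murmur_timing: str = "systolic"    # {"systolic", "continuous"}
    ambient_noise_rms: float = 0.02    # relative to S1 RMS
    seed: int = 0

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        # murmur band tops out at 400 Hz, thrill component below 80 Hz
        if self.sample_rate < 2 * 400:
            raise ValueError("sample_rate must be at least twice the highest "
                             "synthesized frequency (400 Hz)")
        if self.murmur_grade not in GRADES:
            raise ValueError(f"unknown murmur grade {self.murmur_grade!r}; "
                             f"expected one of {GRADES}")
        if self.murmur_timing not in ("systolic", "continuous"):
            raise ValueError(f"unknown murmur timing {self.murmur_timing!r}")
        if self.ambient_noise_rms < 0:
            raise ValueError("ambient_noise_rms must be non-negative")


@dataclass
class Recording:
    """One auscultation-site waveform, normalized to [-1, 1]."""

    patient_id: str
    site: str
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class CohortRecord:
    """One dog: demographics, diagnosis, per-site murmur grades, echo metrics."""

    patient_id: str
    site_of_recruitment: str
    disease: str
    mmvd_stage: str                    # {"none","A","B1","B2","C","D"}
    age: float                         # years
    body_weight: float                 # kg
    bcs: int | None                    # 1-9, None if missing
    sex: str
    heart_rate: float                  # beats/min
    arrhythmia_flag: bool
    levine_grades: dict = field(default_factory=dict)   # site -> 0-6
    point_of_maximal_intensity: str | None = None
    la_ao: float = float("nan")
    lvidd: float = float("nan")
    pimobendan_flag: bool = False
    loop_diuretic_flag: bool = False

    def __post_init__(self):
        for site, lev in self.levine_grades.items():
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")
            if not 0 <= int(lev) <= 6:
                raise ValueError(f"Levine grade out of range at {site}: {lev}")
        if self.body_weight is not None and self.body_weight <= 0:
            raise ValueError("body_weight must be positive")

    @property
    def lviddn(self) -> float:
        """Body-weight-normalized LVIDD: lvidd / weight^0.294."""
        return self.lvidd / self.body_weight ** 0.294

    @property
    def max_levine(self) -> int:
        return max(self.levine_grades.values(), default=0)

    @property
    def max_reduced_grade(self) -> str:
        return reduce_levine(self.max_levine)

    def reduced_grade(self, site: str) -> str:
        return reduce_levine(self.levine_grades.get(site, 0))

    @property
    def has_chf(self) -> bool:
        return self.mmvd_stage in ("C", "D")


def _transient(rng, n, freq, decay, fs):
    """Damped sinusoid transient with a random phase."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * math.pi)
    return np.exp(-t / decay) * np.sin(2 * math.pi * freq * t + phase)


def _band_noise(rng, n, low, high, fs):
    """Unit-RMS Gaussian noise band-passed to [low, high] Hz."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def synthesize_pcg(config: SynthesisConfig, patient_id: str = "synthetic",
                   site: str = "left_apex") -> Recording:
    """Render one phonocardiogram according to ``config``.

    The waveform holds one S1 and one S2 transient per beat at the configured
    heart rate.  A non-``none`` murmur grade adds band-limited (100-400 Hz)
    noise over systole whose RMS, relative to the S1 transient RMS, follows
    :data:`GRADE_RMS_RATIO`; a thrilling murmur additionally carries a
    40-75 Hz component.  Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = round(config.duration * fs)
    beat = 60.0 / config.heart_rate          # seconds per beat
    systole = _SYSTOLE_FRACTION * beat

    s1_len = min(round(0.07 * fs), n)
    s2_len = min(round(0.05 * fs), n)
    x = np.zeros(n)

    s1_rms_parts = []
    t0 = 0.0
    while t0 < config.duration:
        i1 = round(t0 * fs)
        s1 = _transient(rng, s1_len, freq=rng.uniform(80, 110), decay=0.018, fs=fs)
        seg = s1[: n - i1]
        x[i1:i1 + seg.size] += seg
        if seg.size:
            s1_rms_parts.append(np.sqrt(np.mean(s1**2)))
        i2 = round((t0 + systole) * fs)
        if i2 < n:
            s2 = _transient(rng, s2_len, freq=rng.uniform(110, 150), decay=0.012, fs=fs)
            seg = 0.8 * s2[: n - i2]
            x[i2:i2 + seg.size] += seg
        t0 += beat

    s1_rms = float(np.mean(s1_rms_parts)) if s1_rms_parts else 1.0

    ratio = GRADE_RMS_RATIO[config.murmur_grade]
    if ratio > 0:
        noise = _band_noise(rng, n, 100, 400, fs)
        if config.murmur_timing == "continuous":
            gate = np.ones(n)
        else:
            gate = np.zeros(n)
            ramp = round(0.01 * fs)
            t0 = 0.0
            while t0 < config.duration:
                a = round((t0 + 0.06) * fs)          # after the S1 transient
                b = round((t0 + systole - 0.005) * fs)  # before S2
                if a < b:
                    w = np.ones(min(b, n) - min(a, n))
                    r = min(ramp, w.size // 2)
                    if r > 0:
                        edge = 0.5 - 0.5 * np.cos(np.linspace(0, math.pi, r))
                        w[:r] *= edge
                        w[-r:] *= edge[::-1]
                    gate[a:min(b, n)] = w
                t0 += beat
        murmur = noise * gate
        active = gate > 0.5
        act_rms = np.sqrt(np.mean(murmur[active] ** 2)) if active.any() else 1.0
        murmur *= ratio * s1_rms / act_rms
        x += murmur
        if config.murmur_grade == "thrilling":
            thrill = _band_noise(rng, n, 40, 75, fs) * gate
            t_rms = np.sqrt(np.mean(thrill[active] ** 2)) if active.any() else 1.0
            x += thrill * (0.8 * ratio * s1_rms / t_rms)

    if config.ambient_noise_rms > 0:
        x += rng.standard_normal(n) * config.ambient_noise_rms * s1_rms

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return Recording(patient_id=patient_id, site=site, samples=x, sample_rate=fs)


# --------------------------------------------------------------------------
# cohort generation


def _lognormal_from_median_iqr(rng, median, iqr):
    """Sample a log-normal matched to a printed median and interquartile range."""
    lo, hi = iqr
    mu = math.log(median)
    # IQR of a lognormal: exp(mu ± 0.6745 sigma)
    sigma = (math.log(hi) - math.log(lo)) / (2 * 0.6745)
    return float(rng.lognormal(mu, max(sigma, 1e-6)))


def _draw(rng, proportions: dict) -> str:
    keys = list(proportions)
    p = np.array([proportions[k] for k in keys], dtype=float)
    p /= p.sum()
    return keys[rng.choice(len(keys), p=p)]


_DEFAULT_DISEASE_COUNTS = {
    "normal": 134, "MMVD": 407, "PS": 49, "AS": 32, "PDA": 34, "DCM": 24,
    "MVD_dysplasia": 13, "other": 63,
}
_MMVD_STAGE_COUNTS = {"B1": 225, "B2": 131, "C": 44, "D": 7}
_RECRUITMENT_SITES = {"site_1": 0.4, "site_2": 0.3, "site_3": 0.2, "site_4": 0.1}

# grade distributions for diagnoses absent from the printed tables
_GRADE_FALLBACK = {
    "MVD_dysplasia": tables.disease_grade_proportions("MMVD"),
    "other": tables.disease_grade_proportions("DCM"),
}
_PMI_FALLBACK = {
    "MVD_dysplasia": tables.point_of_max_proportions("MMVD"),
    "other": tables.point_of_max_proportions("DCM"),
}

_LEVINE_WITHIN = {"soft": (1, 2), "moderate": (3,), "loud": (4,), "thrilling": (5, 6)}


def default_marginals() -> dict:
    """Default sampling marginals mirroring the published cohort tables."""
    total = sum(_DEFAULT_DISEASE_COUNTS.values())
    stages = sum(_MMVD_STAGE_COUNTS.values())
    return {
        "disease": {k: v / total for k, v in _DEFAULT_DISEASE_COUNTS.items()},
        "mmvd_stage": {k: v / stages for k, v in _MMVD_STAGE_COUNTS.items()},
        "recruitment_site": dict(_RECRUITMENT_SITES),
    }


def _validate_marginals(marginals: dict):
    for name, dist in marginals.items():
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"marginals[{name!r}] sum to {total}, expected 1")


def _stage_column(stage: str) -> str:
    return "C/D" if stage in ("C", "D") else stage


def _sample_echo(rng, stage_col: str):
    """LA/Ao and LVIDDN consistent with the stage's echo criteria."""
    la_med = tables.stage_medians("la_ao")[stage_col]
    lv_med = tables.stage_medians("lviddn")[stage_col]
    for _ in range(200):
        la_ao = _lognormal_from_median_iqr(rng, *la_med)
        lviddn = _lognormal_from_median_iqr(rng, *lv_med)
        if stage_col == "B2" and not (la_ao >= 1.6 and lviddn >= 1.7):
            continue
        if stage_col in ("A", "B1") and (la_ao >= 1.6 and lviddn >= 1.7):
            continue
        return la_ao, lviddn
    raise RuntimeError("echo sampling failed to satisfy stage constraints")


def _sample_demographics(rng, stage_col: str):
    age = _lognormal_from_median_iqr(rng, *tables.stage_medians("age_years")[stage_col])
    weight = _lognormal_from_median_iqr(
        rng, *tables.stage_medians("body_weight_kg")[stage_col])
    t3 = tables.load_table_fixtures("table3")
    n = t3.count("n", stage_col)
    p_lt5 = t3.count("bcs_lt5", stage_col) / n
    p_5to9 = t3.count("bcs_5to9", stage_col) / n
    tot = p_lt5 + p_5to9
    if rng.random() > tot:           # missing BCS, as in the printed table
        bcs = None
    elif rng.random() < p_lt5 / tot:
        bcs = int(rng.integers(3, 5))
    else:
        bcs = int(rng.integers(5, 8))
    sex = _draw(rng, {k: t3.count(k, stage_col) / n for k in
                      ("female_entire", "female_neutered", "male_entire",
                       "male_neutered")})
    arr = rng.random() < t3.count("arrhythmia", stage_col) / n
    return age, weight, bcs, sex, arr


def _site_grades(rng, disease: str, stage_col: str | None):
    """Per-site Levine grades and the point of maximal intensity."""
    if disease == "MMVD":
        max_grade = _draw(rng, tables.stage_grade_proportions(stage_col))
        pmi_site = "left_apex"
    else:
        if disease in tables.DISEASES:
            gdist = tables.disease_grade_proportions(disease)
            pdist = tables.point_of_max_proportions(disease)
        else:
            gdist = _GRADE_FALLBACK[disease]
            pdist = _PMI_FALLBACK[disease]
        max_grade = _draw(rng, gdist)
        sites_only = {k: v for k, v in pdist.items() if k != "none"}
        pmi_site = _draw(rng, sites_only) if sum(sites_only.values()) else "left_apex"

    if max_grade == "none":
        return {s: 0 for s in SITES}, None
    lev_max = int(rng.choice(_LEVINE_WITHIN[max_grade]))
    grades = {}
    for s in SITES:
        if s == pmi_site:
            grades[s] = lev_max
        else:
            grades[s] = max(0, lev_max - int(rng.integers(1, 4)))
    return grades, pmi_site


def synthesize_cohort(n: int, marginals: dict | None = None, seed: int = 0,
                      audio: bool = True,
                      synthesis: SynthesisConfig | None = None,
                      ) -> tuple[list[CohortRecord], list[Recording]]:
    """Generate ``n`` dogs and (optionally) three recordings per dog.

    Each dog receives a diagnosis, an ACVIM stage where applicable, per-site
    Levine grades whose marginals follow the published tables, and echo
    metrics consistent with its stage (B2 satisfies LA/Ao >= 1.6 and
    LVIDDN >= 1.7; A/B1 fail at least one criterion).  Each recording's
    synthesized murmur grade is the reduced form of that site's Levine grade.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    m = default_marginals()
    if marginals:
        m.update(marginals)
    _validate_marginals(m)
    base = synthesis or SynthesisConfig()

    root = np.random.SeedSequence(seed)
    records, recordings = [], []
    for i, ss in enumerate(root.spawn(n)):
        child = ss.generate_state(4)
        rng = np.random.default_rng(child[0])
        pid = f"dog{i:05d}"
        disease = _draw(rng, m["disease"])
        if disease == "MMVD":
            stage = _draw(rng, m["mmvd_stage"])
        else:
            stage = None
        stage_col = _stage_column(stage) if stage else "A"

        age, weight, bcs, sex, arrhythmia = _sample_demographics(rng, stage_col)
        if disease == "normal":
            mmvd_stage = "A" if weight < 15 else "none"
        elif disease == "MMVD":
            mmvd_stage = stage
        else:
            mmvd_stage = "none"

        la_ao, lviddn = _sample_echo(rng, _stage_column(mmvd_stage)
                                     if disease == "MMVD" else "A")
        lvidd = lviddn * weight ** 0.294

        grades, pmi = _site_grades(rng, disease,
                                   _stage_column(stage) if stage else None)
        heart_rate = _lognormal_from_median_iqr(rng, 120, (100, 145))

        t3 = tables.load_table_fixtures("table3")
        if disease == "MMVD":
            p_pimo = t3.count("pimobendan", stage_col) / t3.count("n", stage_col)
        else:
            p_pimo = 0.0
        pimo = rng.random() < p_pimo
        if mmvd_stage in ("C", "D"):
            diuretic = rng.random() < 0.8
        elif mmvd_stage in ("B1", "B2"):
            diuretic = rng.random() < 0.03
        else:
            diuretic = False

        rec = CohortRecord(
            patient_id=pid,
            site_of_recruitment=_draw(rng, m["recruitment_site"]),
            disease=disease, mmvd_stage=mmvd_stage,
            age=age, body_weight=weight, bcs=bcs, sex=sex,
            heart_rate=heart_rate, arrhythmia_flag=arrhythmia,
            levine_grades=grades, point_of_maximal_intensity=pmi,
            la_ao=la_ao, lvidd=lvidd,
            pimobendan_flag=pimo, loop_diuretic_flag=diuretic,
        )
        records.append(rec)

        if audio:
            timing = "continuous" if disease == "PDA" else "systolic"
            for j, site in enumerate(SITES):
                cfg = replace(base, heart_rate=heart_rate,
                              murmur_grade=reduce_levine(grades[site]),
                              murmur_timing=timing,
                              seed=int(child[1] % (2**31)) * 3 + j)
                recordings.append(synthesize_pcg(cfg, patient_id=pid, site=site))
    return records, recordings
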