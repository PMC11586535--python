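"""Normalized log-spectrogram features for the grading network.

A recording is short-time Fourier transformed, magnitude log-compressed with
a small floor, restricted to a frequency band covering both the
low-frequency S1/S2 heart sounds and the higher-frequency murmur band, and
normalized.  Frames are half-open windows starting at sample 0; a trailing
partial frame is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import Recording


@dataclass(frozen=True)
class SpectrogramConfig:
    window_length: int = 200        # samples (50 ms at 4 kHz)
    hop_length: int = 80            # samples (20 ms)
    fft_size: int = 256
    frequency_range: tuple[float, float] = (20.0, 800.0)   # Hz
    log_floor: float = 1e-6
    normalization: str = "per_recording"    # or "per_bin", "none"

    def __post_init__(self):
        if not (0 < self.hop_length <= self.window_length <= self.fft_size):
            raise ValueError("require 0 < hop_length <= window_length <= fft_size")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.normalization not in ("per_recording", "per_bin", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        lo, hi = self.frequency_range
        if not 0 <= lo < hi:
            raise ValueError("frequency_range must satisfy 0 <= low < high")


@dataclass
class Spectrogram:
    """Time x frequency matrix of normalized log magnitudes."""

    values: np.ndarray          # (n_frames, n_bins)
    time_step: float            # seconds between frames
    frequency_step: float       # Hz between bins
    frequencies: np.ndarray     # bin centre frequencies, Hz

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def compute_log_spectrogram(recording: Recording,
                            config: SpectrogramConfig | None = None) -> Spectrogram:
    """Short-time log-magnitude spectrogram of a recording.

    Hann-windowed frames of ``window_length`` samples every ``hop_length``
    samples; magnitudes are compressed as ``log(|X| + log_floor)`` and
    restricted to ``frequency_range`` before normalization.
    """
    cfg = config or SpectrogramConfig()
    x = np.asarray(recording.samples, dtype=np.float64)
    if x.size < cfg.window_length:
        raise ValueError(
            f"recording ({x.size} samples) shorter than one window "
            f"({cfg.window_length} samples)")

    fs = recording.sample_rate
    n_frames = 1 + (x.size - cfg.window_length) // cfg.hop_length
    idx = (np.arange(cfg.window_length)[None, :]
           + cfg.hop_length * np.arange(n_frames)[:, None])
    # symmetric Hann: time-reversing a recording then reverses frame order
    # with per-frame magnitudes preserved exactly
    frames = x[idx] * sps.get_window("hann", cfg.window_length, fftbins=False)
    spec = np.abs(np.fft.rfft(frames, n=cfg.fft_size, axis=1))

    freqs = np.fft.rfftfreq(cfg.fft_size, d=1.0 / fs)
    lo, hi = cfg.frequency_range
    keep = (freqs >= lo) & (freqs <= hi)
    spec = spec[:, keep]
    freqs = freqs[keep]

    values = np.log(spec + cfg.log_floor)
    if cfg.normalization == "per_recording":
        mu, sd = values.mean(), values.std()
        values = (values - mu) / (sd if sd > 0 else 1.0)
    elif cfg.normalization == "per_bin":
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd

    return Spectrogram(values=values,
                       time_step=cfg.hop_length / fs,
                       frequency_step=fs / cfg.fft_size,
                       frequencies=freqs)


#: coarser defaults used by the grading network: shorter sequences make
#: CPU fine-tuning fast while keeping S1/S2 vs murmur bands resolvable
MODEL_SPECTROGRAM = SpectrogramConfig(window_length=400, hop_length=320,
                                      fft_size=512,
                                      frequency_range=(20.0, 800.0))
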