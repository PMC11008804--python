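"""MFCC front-end and frame/time index mapping.

Audio is framed with a Hann window (no pre-padding), passed through a mel
filterbank, log-compressed, and decorrelated with an orthonormal DCT-II.
Defaults are the common ASR front-end: 13 cepstra, 26 mel filters, 25 ms
window, 10 ms hop at 16 kHz.

Per-recording z-normalization of each cepstral column (mean 0, population
SD 1) removes the loudness dependence of the features before DTW matching:
a global gain multiplies the power spectrum by a constant, which shifts
only the 0th cepstrum additively, and the column-wise centering cancels it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

__all__ = [
    "MFCCConfig",
    "MFCCMatrix",
    "compute_mfcc",
    "znormalize",
    "frame_to_time",
    "time_to_frame",
    "n_frames_for",
]


@dataclass(frozen=True)
class MFCCConfig:
    """Front-end parameters.

    n_coefficients: cepstra kept per frame (includes the 0th / energy term).
    window_s / hop_s: analysis window length and frame step, seconds.
    n_mel_filters: triangular filters spanning 0 .. sample_rate/2.
    sample_rate: rate the signal must have (Hz); callers resample first.
    """

    n_coefficients: int = 13
    window_s: float = 0.025
    hop_s: float = 0.010
    n_mel_filters: int = 26
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.window_s):
            raise ValueError("require 0 < hop_s <= window_s")
        if self.n_coefficients > self.n_mel_filters:
            raise ValueError("n_coefficients must not exceed n_mel_filters")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_s * self.sample_rate))


@dataclass(frozen=True)
class MFCCMatrix:
    """Frames x coefficients cepstral matrix with its framing metadata."""

    values: np.ndarray
    hop_s: float
    window_s: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"expected 2-D matrix, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("MFCC matrix contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.values.shape[1]


def n_frames_for(n_samples: int, config: MFCCConfig) -> int:
    """Frame count for non-padded framing: 1 + floor((n - window) / hop)."""
    return 1 + (n_samples - config.window_samples) // config.hop_samples


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filters, (n_filters, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2.0),
                          n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fbank = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for k in range(lo, mid):
            if mid > lo:
                fbank[i, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fbank[i, k] = (hi - k) / (hi - mid)
    return fbank


def compute_mfcc(signal, config: MFCCConfig | None = None) -> MFCCMatrix:
    """Compute the MFCC matrix of a mono signal.

    The signal must already be at ``config.sample_rate`` and at least one
    window long.  Deterministic: identical input gives identical output.
    """
    config = config or MFCCConfig()
    if signal.sample_rate != config.sample_rate:
        raise ValueError(
            f"signal rate {signal.sample_rate} != config rate "
            f"{config.sample_rate}; resample first"
        )
    x = signal.samples
    win, hop = config.window_samples, config.hop_samples
    if len(x) < win:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {win}-sample window"
        )
    n_frames = n_frames_for(len(x), config)
    idx = hop * np.arange(n_frames)[:, None] + np.arange(win)[None, :]
    frames = x[idx] * np.hanning(win)[None, :]

    n_fft = int(2 ** np.ceil(np.log2(win)))
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fbank = _mel_filterbank(config.n_mel_filters, n_fft, config.sample_rate)
    mel_energy = power @ fbank.T
    log_mel = np.log(np.maximum(mel_energy, 1e-12))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)[:, : config.n_coefficients]
    return MFCCMatrix(values=cepstra, hop_s=config.hop_s, window_s=config.window_s)


def znormalize(mfcc: MFCCMatrix) -> MFCCMatrix:
    """Column-wise zero mean, unit population SD; constant columns -> zeros."""
    if mfcc.n_frames < 2:
        raise ValueError("z-normalization needs at least 2 frames")
    mean = mfcc.values.mean(axis=0)
    sd = mfcc.values.std(axis=0)  # population SD
    centered = mfcc.values - mean
    out = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return MFCCMatrix(values=out, hop_s=mfcc.hop_s, window_s=mfcc.window_s)


def frame_to_time(frame_index: int, hop_s: float, window_s: float) -> float:
    """Center time of a 0-based frame: frame * hop + window / 2."""
    return frame_index * hop_s + window_s / 2.0


def time_to_frame(t_s: float, hop_s: float, window_s: float,
                  n_frames: int | None = None) -> int:
    """Nearest frame whose center is at ``t_s``; clamped to the valid range.

    Inverse of :func:`frame_to_time` on frame centers.
    """
    frame = int(round((t_s - window_s / 2.0) / hop_s))
    frame = max(frame, 0)
    if n_frames is not None:
        frame = min(frame, n_frames - 1)
    return frame
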