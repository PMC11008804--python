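"""Waveform and annotation I/O, amplitude conditioning, cropping.

Audio is carried through the pipeline as :class:`AudioSignal` — a mono
float64 waveform in the nominal range [-1, 1] with its sample rate.
Repetition annotations (one time interval per phrase repetition) are
carried as :class:`ParseAnnotation` and round-trip through a small CSV
format with header ``recording_id,repetition_index,onset_s,offset_s``.

Conventions (the clinical recordings' native format is not standardized,
so these are fixed here once):

* intervals are half-open ``[onset, offset)`` in seconds; the sample index
  of a time ``t`` is ``round(t * rate)``;
* WAV files are written as 16-bit PCM; higher bit depths and float WAV are
  accepted on read;
* multi-channel audio is averaged down to mono on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AnnotationError, AudioFormatError, SilentSignalError

__all__ = [
    "AudioSignal",
    "RepetitionInterval",
    "ParseAnnotation",
    "read_wav",
    "write_wav",
    "resample",
    "peak_normalize",
    "crop",
    "concatenate",
    "time_stretch",
    "read_parse_csv",
    "write_parse_csv",
    "write_textgrid",
]

PARSE_CSV_HEADER = ["recording_id", "repetition_index", "onset_s", "offset_s"]


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform with sample rate.

    Parameters
    ----------
    samples
        Amplitude values, nominal range [-1, 1].
    sample_rate
        Samples per second (Hz), > 0.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError(f"expected mono signal, got shape {samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class RepetitionInterval:
    """Half-open time interval [onset_s, offset_s) of one phrase repetition."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s < self.offset_s):
            raise AnnotationError(
                f"invalid interval: onset {self.onset_s} must satisfy "
                f"0 <= onset < offset ({self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class ParseAnnotation:
    """Ordered, non-overlapping repetition intervals for one recording."""

    recording_id: str
    intervals: tuple[RepetitionInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        intervals = tuple(self.intervals)
        for i in range(1, len(intervals)):
            if intervals[i].onset_s < intervals[i - 1].offset_s:
                raise AnnotationError(
                    f"{self.recording_id}: interval {i + 1} (onset "
                    f"{intervals[i].onset_s}) overlaps interval {i} "
                    f"(offset {intervals[i - 1].offset_s})"
                )
        object.__setattr__(self, "intervals", intervals)

    @property
    def count(self) -> int:
        return len(self.intervals)


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1] floats; pass floats through."""
    if samples.dtype.kind == "f":
        return samples.astype(np.float64)
    if samples.dtype.kind in "iu":
        info = np.iinfo(samples.dtype)
        # unsigned PCM (8-bit WAV) is offset-binary
        if samples.dtype.kind == "u":
            half = (info.max + 1) / 2
            return (samples.astype(np.float64) - half) / half
        return samples.astype(np.float64) / (abs(info.min))
    raise AudioFormatError(f"unsupported WAV sample dtype {samples.dtype}")


def read_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF/WAV file as a mono float signal in [-1, 1].

    Multi-channel input is averaged to mono. Raises
    :class:`FileNotFoundError` for a missing file, :class:`AudioFormatError`
    for non-WAV content, and :class:`SilentSignalError` for a zero-length
    stream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.size == 0:
        raise SilentSignalError(f"{path} contains a zero-length audio stream")
    data = np.atleast_1d(data)
    if data.ndim == 2:
        data = _to_float(data).mean(axis=1)
    else:
        data = _to_float(data)
    return AudioSignal(samples=data, sample_rate=int(rate))


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write a signal as 16-bit PCM WAV (values clipped to [-1, 1])."""
    if len(signal) == 0:
        raise SilentSignalError("refusing to write an empty signal")
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(Path(path)), signal.sample_rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resample to ``target_rate``; duration preserved within one sample."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.sample_rate:
        return signal
    ratio = Fraction(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(samples=out, sample_rate=int(target_rate))


def peak_normalize(signal: AudioSignal, target_peak: float = 1.0) -> AudioSignal:
    """Scale so max |sample| equals ``target_peak`` (shape preserved)."""
    peak = float(np.max(np.abs(signal.samples))) if len(signal) else 0.0
    if peak == 0.0:
        raise SilentSignalError("cannot peak-normalize an all-zero (silent) signal")
    return AudioSignal(samples=signal.samples * (target_peak / peak),
                       sample_rate=signal.sample_rate)


def crop(signal: AudioSignal, onset_s: float, offset_s: float) -> AudioSignal:
    """Half-open slice [onset_s, offset_s) by sample index round(t * rate)."""
    if not (0.0 <= onset_s < offset_s <= signal.duration_s + 0.5 / signal.sample_rate):
        raise ValueError(
            f"crop bounds [{onset_s}, {offset_s}) out of range for "
            f"{signal.duration_s:.6f} s signal"
        )
    i = int(round(onset_s * signal.sample_rate))
    j = int(round(offset_s * signal.sample_rate))
    j = min(j, len(signal))
    return AudioSignal(samples=signal.samples[i:j].copy(), sample_rate=signal.sample_rate)


def concatenate(signals: list[AudioSignal]) -> AudioSignal:
    """Concatenate signals sharing one sample rate."""
    if not signals:
        raise ValueError("cannot concatenate an empty list of signals")
    rates = {s.sample_rate for s in signals}
    if len(rates) != 1:
        raise ValueError(f"sample-rate mismatch in concatenate: {sorted(rates)}")
    return AudioSignal(samples=np.concatenate([s.samples for s in signals]),
                       sample_rate=signals[0].sample_rate)


def time_stretch(signal: AudioSignal, factor: float) -> AudioSignal:
    """Uniformly stretch duration by ``factor`` via band-limited interpolation.

    The output has ``round(factor * n)`` samples at the original rate, so a
    boundary at time ``t`` in the input maps to ``factor * t``.  (Pitch is
    not preserved; frequencies scale by ``1/factor``.)
    """
    if factor <= 0:
        raise ValueError(f"stretch factor must be positive, got {factor}")
    frac = Fraction(factor).limit_denominator(1000)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(samples=out, sample_rate=signal.sample_rate)


def read_parse_csv(path: str | Path) -> ParseAnnotation:
    """Read a parse annotation CSV; validates ordering and overlap row by row."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != PARSE_CSV_HEADER:
            raise AnnotationError(
                f"{path}: expected header {','.join(PARSE_CSV_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        rows = list(reader)
    recording_id = rows[0]["recording_id"] if rows else path.stem
    intervals = []
    for k, row in enumerate(rows, start=1):
        try:
            interval = RepetitionInterval(float(row["onset_s"]), float(row["offset_s"]))
        except AnnotationError as exc:
            raise AnnotationError(f"{path} row {k}: {exc}") from exc
        if intervals and interval.onset_s < intervals[-1].offset_s:
            raise AnnotationError(
                f"{path} row {k}: interval overlaps or precedes the previous row"
            )
        intervals.append(interval)
    return ParseAnnotation(recording_id=recording_id, intervals=tuple(intervals))


def write_parse_csv(annotation: ParseAnnotation, path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PARSE_CSV_HEADER)
        for k, interval in enumerate(annotation.intervals, start=1):
            writer.writerow(
                [annotation.recording_id, k,
                 f"{interval.onset_s:.6f}", f"{interval.offset_s:.6f}"]
            )


def write_textgrid(annotation: ParseAnnotation, duration_s: float,
                   path: str | Path) -> None:
    """Export as a Praat TextGrid with one interval tier named "repetition".

    Gaps between repetitions become empty-label intervals so the tier tiles
    [0, duration_s] as Praat expects.
    """
    tiles: list[tuple[float, float, str]] = []
    cursor = 0.0
    for k, iv in enumerate(annotation.intervals, start=1):
        if iv.onset_s > cursor:
            tiles.append((cursor, iv.onset_s, ""))
        tiles.append((iv.onset_s, iv.offset_s, str(k)))
        cursor = iv.offset_s
    if cursor < duration_s:
        tiles.append((cursor, duration_s, ""))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {duration_s:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "repetition"',
        "        xmin = 0",
        f"        xmax = {duration_s:.6f}",
        f"        intervals: size = {len(tiles)}",
    ]
    for k, (a, b, label) in enumerate(tiles, start=1):
        lines += [
            f"        intervals [{k}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{label}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
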