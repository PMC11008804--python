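"""Reference bank: recordings with 1..N repetitions and exact boundaries.

A single parsed source recording (in practice a healthy-control speaker
held out from any evaluation) is cropped into its individual repetitions,
and entry ``k`` of the bank concatenates ``k`` of those crops — cycling
through the source repetitions in order when ``k`` exceeds the source
count — separated by a fixed silent pause.  Entry ``k``'s annotation is
exact by construction (cumulative arithmetic of crop lengths and pauses),
which is what makes boundary transfer through a warping path meaningful.

A bank persists as a plain directory of WAV + parse-CSV pairs plus a
``manifest.csv`` (columns: count, wav, csv, duration_s) so it can be
inspected and shared.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_io import (
    AudioSignal,
    ParseAnnotation,
    RepetitionInterval,
    concatenate,
    crop,
    peak_normalize,
    read_parse_csv,
    read_wav,
    write_parse_csv,
    write_wav,
)
from .errors import CountOutOfRangeError

__all__ = ["ReferenceBank", "build_bank", "select_reference", "save_bank", "load_bank"]

DEFAULT_MAX_COUNT = 13
DEFAULT_PAUSE_S = 0.3


@dataclass(frozen=True)
class ReferenceBank:
    """Map from repetition count k to (audio, exact parse), k = 1..max_count."""

    entries: dict[int, tuple[AudioSignal, ParseAnnotation]]

    def __post_init__(self) -> None:
        counts = sorted(self.entries)
        if counts != list(range(1, len(counts) + 1)):
            raise ValueError(f"bank counts must be contiguous 1..N, got {counts}")
        for k, (_, parse) in self.entries.items():
            if parse.count != k:
                raise ValueError(
                    f"bank entry {k} carries {parse.count} intervals"
                )

    @property
    def max_count(self) -> int:
        return len(self.entries)


def build_bank(source: AudioSignal, source_parse: ParseAnnotation,
               max_count: int = DEFAULT_MAX_COUNT,
               pause_s: float = DEFAULT_PAUSE_S) -> ReferenceBank:
    """Construct the bank from one parsed source recording.

    The source is peak-normalized first, then each entry ``k`` is the
    concatenation of ``k`` repetition crops (cycling in order past the
    source count) separated by ``pause_s`` of silence.
    """
    if source_parse.count < 1:
        raise ValueError("source parse must contain at least one repetition")
    if max_count < 1:
        raise ValueError(f"max_count must be >= 1, got {max_count}")
    normalized = peak_normalize(source)
    reps = [crop(normalized, iv.onset_s, iv.offset_s) for iv in source_parse.intervals]
    pause = AudioSignal(
        samples=np.zeros(int(round(pause_s * source.sample_rate))),
        sample_rate=source.sample_rate,
    )
    entries: dict[int, tuple[AudioSignal, ParseAnnotation]] = {}
    for k in range(1, max_count + 1):
        pieces: list[AudioSignal] = []
        intervals: list[RepetitionInterval] = []
        cursor = 0.0
        for i in range(k):
            rep = reps[i % len(reps)]
            if i > 0:
                pieces.append(pause)
                cursor += len(pause) / pause.sample_rate
            pieces.append(rep)
            dur = len(rep) / rep.sample_rate
            intervals.append(RepetitionInterval(cursor, cursor + dur))
            cursor += dur
        entries[k] = (
            concatenate(pieces),
            ParseAnnotation(recording_id=f"ref_{k:02d}", intervals=tuple(intervals)),
        )
    return ReferenceBank(entries=entries)


def select_reference(bank: ReferenceBank, count: int) -> tuple[AudioSignal, ParseAnnotation]:
    """Entry with the requested repetition count; strict range check.

    An out-of-range count signals an implausible transcript-derived count;
    pipeline callers may clamp to [1, max_count] before calling (the
    default CLI policy), but this lookup itself never clamps.
    """
    if not (1 <= count <= bank.max_count):
        raise CountOutOfRangeError(
            f"requested count {count} outside bank range 1..{bank.max_count}"
        )
    return bank.entries[count]


def save_bank(bank: ReferenceBank, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k in range(1, bank.max_count + 1):
        audio, parse = bank.entries[k]
        wav_name, csv_name = f"ref_{k:02d}.wav", f"ref_{k:02d}.csv"
        write_wav(audio, directory / wav_name)
        write_parse_csv(parse, directory / csv_name)
        rows.append([k, wav_name, csv_name, f"{audio.duration_s:.6f}"])
    with open(directory / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["count", "wav", "csv", "duration_s"])
        writer.writerows(rows)


def load_bank(directory: str | Path) -> ReferenceBank:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no bank manifest at {manifest}")
    entries: dict[int, tuple[AudioSignal, ParseAnnotation]] = {}
    with open(manifest, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            k = int(row["count"])
            entries[k] = (
                read_wav(directory / row["wav"]),
                read_parse_csv(directory / row["csv"]),
            )
    return ReferenceBank(entries=entries)
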