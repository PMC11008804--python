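"""Transcriber contract, text normalization, WER, and repetition counting.

The acoustic model itself is pluggable: anything that maps an
:class:`~repseg.audio_io.AudioSignal` to a :class:`Transcript` satisfies
the transcriber contract (a fine-tuned wav2vec-style ASR in production; a
deterministic seeded mock in tests and simulations).

Repetition counting scans the transcript left to right with a greedy
fuzzy window matcher: at each position, candidate windows of length
``len(phrase) +/- 1`` are scored against the target phrase and the best
window is accepted if its dissimilarity is at or below a threshold.
Window dissimilarity uses character-aware substitution costs (normalized
character edit distance between tokens) so near-miss recognitions of a
word ("boby" for "bobby") count as partial rather than full errors; the
reported WER metric itself remains the classical unit-cost word-level
error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .audio_io import AudioSignal, ParseAnnotation

__all__ = [
    "Transcript",
    "WERResult",
    "Transcriber",
    "DEFAULT_PHRASE",
    "normalize_text",
    "word_error_rate",
    "count_phrase_repetitions",
    "window_dissimilarity",
    "mock_transcriber",
]

#: The phrase repeated in the orofacial examination task.
DEFAULT_PHRASE = ("buy", "bobby", "a", "puppy")

Transcript = tuple[str, ...]

# punctuation maps to whitespace so "bobby,a" still splits into two tokens
_PUNCT = str.maketrans({c: " " for c in r"""!"#$%&'()*+,./:;<=>?@[\]^_`{|}~"""})


class Transcriber(Protocol):
    """Callable contract: audio in, lowercase word tokens out."""

    def __call__(self, audio: AudioSignal) -> Transcript: ...


@dataclass(frozen=True)
class WERResult:
    """Word-level minimum-edit-distance alignment summary."""

    substitutions: int
    deletions: int
    insertions: int
    reference_length: int

    @property
    def wer_percent(self) -> float:
        return 100.0 * (self.substitutions + self.deletions + self.insertions) \
            / self.reference_length


def normalize_text(raw: str) -> Transcript:
    """Lowercase, strip punctuation, split on whitespace."""
    return tuple(raw.translate(_PUNCT).lower().split())


def _edit_ops(reference: Sequence[str], hypothesis: Sequence[str]) -> tuple[int, int, int]:
    """(S, D, I) of a minimum word edit alignment, unit costs.

    Ties broken preferring substitution over deletion over insertion, so
    the decomposition is deterministic.
    """
    n, m = len(reference), len(hypothesis)
    dist = np.zeros((n + 1, m + 1), dtype=np.int64)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1, j - 1] + (reference[i - 1] != hypothesis[j - 1])
            dist[i, j] = min(sub, dist[i - 1, j] + 1, dist[i, j - 1] + 1)
    s = d = ins = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + (
            reference[i - 1] != hypothesis[j - 1]
        ):
            s += reference[i - 1] != hypothesis[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return s, d, ins


def word_error_rate(reference: Transcript, hypothesis: Transcript) -> WERResult:
    """Classical WER: 100 * (S + D + I) / |reference|."""
    if len(reference) == 0:
        raise ValueError("WER is undefined for an empty reference")
    s, d, ins = _edit_ops(reference, hypothesis)
    return WERResult(substitutions=s, deletions=d, insertions=ins,
                     reference_length=len(reference))


def _char_distance(a: str, b: str) -> int:
    """Character Levenshtein distance (unit costs)."""
    if a == b:
        return 0
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j - 1] + (a[i - 1] != b[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[m]


def window_dissimilarity(phrase: Sequence[str], window: Sequence[str]) -> float:
    """Edit cost of ``window`` against ``phrase``, scaled by |phrase|.

    Substituting token a for token b costs the normalized character edit
    distance dist(a, b) / max(|a|, |b|); insertions and deletions cost 1.
    Zero iff the window equals the phrase exactly.
    """
    n, m = len(phrase), len(window)
    dist = np.zeros((n + 1, m + 1))
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a, b = phrase[i - 1], window[j - 1]
            sub_cost = _char_distance(a, b) / max(len(a), len(b))
            dist[i, j] = min(dist[i - 1, j - 1] + sub_cost,
                             dist[i - 1, j] + 1.0, dist[i, j - 1] + 1.0)
    return float(dist[n, m]) / n


def count_phrase_repetitions(transcript: Transcript, phrase: Transcript,
                             max_window_wer: float = 0.5) -> int:
    """Count non-overlapping fuzzy occurrences of ``phrase`` in ``transcript``.

    Greedy left-to-right scan: at each position, windows of length
    ``len(phrase) - 1 .. len(phrase) + 1`` are scored with
    :func:`window_dissimilarity`; the minimum-score window is accepted when
    its score is <= ``max_window_wer`` (ties prefer the exact phrase
    length, then the shorter window), and the scan resumes past it.
    Otherwise the scan advances one token.
    """
    if len(phrase) == 0:
        raise ValueError("phrase must be non-empty")
    if not (0.0 <= max_window_wer < 1.0):
        raise ValueError("max_window_wer must lie in [0, 1)")
    # candidate lengths in tie-break preference order
    lengths = [len(phrase), max(1, len(phrase) - 1), len(phrase) + 1]
    count = 0
    pos = 0
    while pos < len(transcript):
        best_len, best_score = None, np.inf
        for length in lengths:
            if pos + length > len(transcript):
                continue
            score = window_dissimilarity(phrase, transcript[pos:pos + length])
            if score < best_score - 1e-12:
                best_len, best_score = length, score
        if best_len is not None and best_score <= max_window_wer:
            count += 1
            pos += best_len
        else:
            pos += 1
    return count


def mock_transcriber(annotation: ParseAnnotation, word_error_prob: float = 0.0,
                     seed: int = 0,
                     phrase: Transcript = DEFAULT_PHRASE) -> Callable[[AudioSignal], Transcript]:
    """Deterministic test double for the ASR stage.

    Returns a transcriber that ignores the waveform and emits one phrase
    copy per annotated repetition, with each word independently corrupted
    (substituted or deleted, chosen with equal probability) with
    probability ``word_error_prob``, all driven by ``seed``.
    """
    if not (0.0 <= word_error_prob <= 1.0):
        raise ValueError("word_error_prob must lie in [0, 1]")

    def transcribe(audio: AudioSignal) -> Transcript:
        rng = np.random.default_rng(seed)
        tokens: list[str] = []
        for _ in range(annotation.count):
            for word in phrase:
                if rng.random() < word_error_prob:
                    if rng.random() < 0.5:
                        continue  # deletion
                    tokens.append(_corrupt_word(word, rng))
                else:
                    tokens.append(word)
        return tuple(tokens)

    return transcribe


def _corrupt_word(word: str, rng: np.random.Generator) -> str:
    """Single random character edit: a plausible near-miss recognition."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    pos = int(rng.integers(0, len(word)))
    op = rng.random()
    if op < 1 / 3 and len(word) > 1:
        return word[:pos] + word[pos + 1:]
    if op < 2 / 3:
        return word[:pos] + letters[int(rng.integers(0, 26))] + word[pos + 1:]
    return word[:pos] + letters[int(rng.integers(0, 26))] + word[pos:]
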