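"""Synthetic repeated-phrase recordings with exact ground-truth parses.

Real recordings of the repeated-phrase task consist of one speaker saying
the same short phrase K times with short pauses, under elicitation
conditions that vary speaking rate (normal, roughly double, roughly half)
and loudness (normal, loud).  The generator emulates exactly that
structure: each "phrase token" is a sequence of four syllable-like
harmonic bursts — a glottal-pulse-style harmonic stack shaped by a
syllable-specific formant resonance and an amplitude envelope — so that
consecutive MFCC frames differ and DTW alignment is non-degenerate, while
everything stays fully seeded and reproducible.

Formant targets per syllable position are shared across synthetic speakers
(everyone says the same phrase) with per-speaker jitter, and fundamental
frequency varies per speaker; this is what makes cross-speaker DTW
matching meaningful, as it is for real same-phrase recordings.

What this generator does NOT emulate: articulatory detail, consonant
noise, channel/room effects, or any specific dysarthria subtype.  Passing
end-to-end tests on this material demonstrates the alignment and
evaluation machinery, not clinical ASR performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSignal, ParseAnnotation, RepetitionInterval
from .transcription import DEFAULT_PHRASE, Transcript

__all__ = [
    "SynthSpec",
    "CorpusRecord",
    "CONDITIONS",
    "synth_token",
    "synth_recording",
    "make_emulated_corpus",
    "corrupt_transcript",
]

#: Elicitation conditions: (label, rate_factor, loudness_db).
CONDITIONS = (
    ("normal", 1.0, 0.0),
    ("fast", 2.0, 0.0),
    ("slow", 0.5, 0.0),
    ("loud", 1.0, 6.0),
)

BASE_TOKEN_S = 1.2          # duration of one phrase token at rate 1
N_SYLLABLES = 4
#: Shared formant-like resonance targets (Hz), one per syllable position.
SYLLABLE_FORMANTS = (550.0, 950.0, 1500.0, 2300.0)
DURATION_JITTER = 0.10      # +/-10% per-repetition duration jitter


@dataclass(frozen=True)
class SynthSpec:
    """One synthetic recording's generation parameters."""

    n_repetitions: int = 5
    rate_factor: float = 1.0        # 1 normal, ~2 fast, ~0.5 slow
    loudness_db: float = 0.0        # gain re: normal
    pause_s: float = 0.3
    noise_snr_db: float = 40.0      # quiet-room recording floor; inf = ideal
    sample_rate: int = 16000
    seed: int = 0
    voice_seed: int | None = None   # None: derive the voice from `seed`

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.rate_factor <= 0:
            raise ValueError("rate_factor must be positive")
        if self.pause_s < 0:
            raise ValueError("pause_s must be non-negative")


@dataclass(frozen=True)
class CorpusRecord:
    recording_id: str
    condition: str
    n_repetitions: int
    audio: AudioSignal
    annotation: ParseAnnotation
    seed: int


@dataclass(frozen=True)
class Voice:
    """A synthetic speaker's fixed vocal characteristics."""

    f0: float                       # fundamental frequency, Hz
    formants: tuple[float, ...]     # per-syllable resonance targets, Hz

    @classmethod
    def from_seed(cls, seed: int) -> "Voice":
        rng = np.random.default_rng(seed)
        f0 = float(rng.uniform(100.0, 220.0))
        jitter = rng.uniform(0.95, 1.05, N_SYLLABLES)
        return cls(f0=f0, formants=tuple(np.array(SYLLABLE_FORMANTS) * jitter))


def synth_token(rate_factor: float = 1.0, sample_rate: int = 16000,
                seed: int = 0, duration_jitter: float = 0.0,
                voice: Voice | None = None) -> AudioSignal:
    """One pseudo-phrase token: 4 enveloped harmonic syllable bursts.

    Total duration is ``BASE_TOKEN_S / rate_factor`` (optionally jittered
    by a seeded factor in ``1 +/- duration_jitter``); ``rate_factor``
    scales durations only, never frequencies, as a speaker talking faster
    would.  The voice (f0, formant placement) is fixed per speaker; the
    seed drives phases and duration jitter so repetitions vary naturally.
    """
    if rate_factor <= 0:
        raise ValueError("rate_factor must be positive")
    rng = np.random.default_rng(seed)
    voice = voice or Voice.from_seed(seed)
    f0 = voice.f0
    formants = np.asarray(voice.formants)
    stretch = 1.0 + rng.uniform(-duration_jitter, duration_jitter)
    duration = BASE_TOKEN_S * stretch / rate_factor
    syl_dur = duration / N_SYLLABLES
    pieces = []
    for syl in range(N_SYLLABLES):
        n = int(round(syl_dur * sample_rate))
        # equalize rounding so the token hits its target length exactly
        if syl == N_SYLLABLES - 1:
            n = int(round(duration * sample_rate)) - sum(len(p) for p in pieces)
        t = np.arange(n) / sample_rate
        burst = np.zeros(n)
        # harmonic stack up to ~0.45 * Nyquist so every formant target is
        # excited regardless of the speaker's f0
        n_harmonics = int(0.45 * sample_rate / f0)
        for h in range(1, n_harmonics + 1):
            freq = h * f0
            # formant-shaped harmonic weighting
            weight = np.exp(-((freq - formants[syl]) ** 2) / (2 * 350.0 ** 2))
            weight += 0.02  # spectral floor so low harmonics never vanish
            burst += weight * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        envelope = np.hanning(max(n, 2))[:n] ** 0.5
        pieces.append(burst * envelope)
    token = np.concatenate(pieces)
    peak = np.max(np.abs(token))
    return AudioSignal(samples=0.5 * token / peak, sample_rate=sample_rate)


def synth_recording(spec: SynthSpec) -> tuple[AudioSignal, ParseAnnotation]:
    """Render one recording: tokens separated by pauses, gain, noise.

    The annotation intervals bracket the non-silent token spans exactly.
    """
    rng = np.random.default_rng(spec.seed)
    voice = Voice.from_seed(spec.voice_seed if spec.voice_seed is not None
                            else spec.seed)
    gain = 10.0 ** (spec.loudness_db / 20.0)
    pieces: list[np.ndarray] = []
    intervals: list[RepetitionInterval] = []
    cursor_samples = 0
    for rep in range(spec.n_repetitions):
        token = synth_token(
            rate_factor=spec.rate_factor, sample_rate=spec.sample_rate,
            seed=int(rng.integers(0, 2**31)), duration_jitter=DURATION_JITTER,
            voice=voice,
        )
        if rep > 0:
            pause_len = int(round(
                spec.pause_s * (1 + rng.uniform(-DURATION_JITTER, DURATION_JITTER))
                * spec.sample_rate
            ))
            pieces.append(np.zeros(pause_len))
            cursor_samples += pause_len
        onset = cursor_samples / spec.sample_rate
        pieces.append(token.samples)
        cursor_samples += len(token)
        intervals.append(RepetitionInterval(onset, cursor_samples / spec.sample_rate))
    samples = np.concatenate(pieces) * gain
    if math.isfinite(spec.noise_snr_db):
        signal_power = float(np.mean(samples**2))
        noise_power = signal_power / (10.0 ** (spec.noise_snr_db / 10.0))
        samples = samples + rng.normal(0.0, math.sqrt(noise_power), len(samples))
    audio = AudioSignal(samples=samples, sample_rate=spec.sample_rate)
    annotation = ParseAnnotation(
        recording_id=f"synth_{spec.seed}", intervals=tuple(intervals)
    )
    return audio, annotation


def make_emulated_corpus(n_speakers: int, seed: int = 0,
                         sample_rate: int = 16000) -> list[CorpusRecord]:
    """One recording per elicitation condition per synthetic speaker.

    Each recording has 4-6 repetitions (seeded), matching the elicitation
    protocol of roughly five repetitions with short pauses.
    """
    if n_speakers < 1:
        raise ValueError("n_speakers must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for speaker in range(n_speakers):
        voice_seed = int(rng.integers(0, 2**31))
        for condition, rate_factor, loudness_db in CONDITIONS:
            n_reps = int(rng.integers(4, 7))
            rec_seed = int(rng.integers(0, 2**31))
            spec = SynthSpec(
                n_repetitions=n_reps, rate_factor=rate_factor,
                loudness_db=loudness_db, sample_rate=sample_rate,
                seed=rec_seed, voice_seed=voice_seed,
            )
            audio, annotation = synth_recording(spec)
            rec_id = f"spk{speaker:02d}_{condition}"
            records.append(CorpusRecord(
                recording_id=rec_id, condition=condition, n_repetitions=n_reps,
                audio=audio,
                annotation=ParseAnnotation(recording_id=rec_id,
                                           intervals=annotation.intervals),
                seed=rec_seed,
            ))
    return records


def corrupt_transcript(true_count: int, phrase: Transcript = DEFAULT_PHRASE,
                       word_error_prob: float = 0.0, seed: int = 0,
                       deletion_only: bool = False) -> Transcript:
    """``true_count`` phrase copies with seeded word-level corruption.

    Each word is independently substituted (by a random non-phrase token)
    or deleted, each with probability ``word_error_prob / 2``; with
    ``deletion_only`` the whole error mass goes to deletions.
    """
    if not (0.0 <= word_error_prob <= 1.0):
        raise ValueError("word_error_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    filler = ("the", "dog", "happy", "mum", "pop", "bye")
    tokens: list[str] = []
    for _ in range(true_count):
        for word in phrase:
            u = rng.random()
            if u < word_error_prob / 2 or (deletion_only and u < word_error_prob):
                continue
            if not deletion_only and u < word_error_prob:
                tokens.append(filler[int(rng.integers(0, len(filler)))])
            else:
                tokens.append(word)
    return tuple(tokens)
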