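# Methods

This note documents the models, parameter choices, and numerical details
behind `repseg`, and what the synthetic experiments do and do not show.

## Pipeline model

A recording of one speaker repeating a fixed phrase K times is segmented
in four stages:

1. **Repetition counting.** The transcript (from any external ASR, or the
   deterministic mock) is lowercased, punctuation becomes whitespace, and
   a greedy left-to-right matcher scans the token stream. At each position
   it scores windows of length |phrase|±1 against the target phrase and
   accepts the best window when its dissimilarity is ≤ a threshold
   (default 0.5), then resumes past it; otherwise it advances one token.
   Window dissimilarity is a word-level edit cost in which substituting
   token *a* for *b* costs the character Levenshtein distance divided by
   max(|a|, |b|) (insertions/deletions cost 1), normalized by |phrase|.
   The character-aware substitution cost is deliberate: dysarthric-speech
   ASR output is dominated by near-miss recognitions ("boby" for
   "bobby"), which should count as partial, not total, mismatches. At
   threshold 0 the matcher reduces exactly to an exact substring scan
   (property-tested). How counts are derived from transcripts is a design
   choice of this package; window lengths |phrase|±1 tolerate one
   insertion or deletion inside a repetition.

2. **Reference selection.** A bank holds recordings with 1..13
   repetitions and exactly known boundaries, built by cropping the
   repetitions out of one parsed source recording (peak-normalized
   first) and concatenating k of them, cycling through the source
   repetitions in order when k exceeds the source count, separated by
   0.3 s of inserted silence. Cycling preserves the source's natural
   duration variability; silence insertion (rather than carrying
   surrounding audio) makes entry boundaries exact by arithmetic.
   Out-of-range counts are clamped to [1, 13] with a warning at the
   pipeline level (strict mode errors instead), so an implausible ASR
   count still produces a parse.

3. **Alignment.** Both signals are resampled to 16 kHz, peak-normalized,
   and converted to MFCCs: 25 ms Hann window, 10 ms hop, no pre-padding
   (frames = 1 + ⌊(n − window)/hop⌋), 512-point FFT, 26 triangular mel
   filters spanning 0–8 kHz, log floor 1e−12, orthonormal DCT-II, 13
   cepstra. Each cepstral column is z-normalized per recording with the
   population SD; zero-variance columns map to zero rather than erroring
   so silent-segment columns stay usable. Peak normalization plus
   column-wise centering makes the features exactly gain-invariant: a
   global gain shifts only the 0th cepstrum additively and centering
   cancels it. DTW minimizes accumulated Euclidean frame distance with
   steps {(1,0),(0,1),(1,1)}, unit weights, no band by default (a
   Sakoe–Chiba band is available for speed). Backtracking prefers
   diagonal, then reference-advancing steps, so paths are deterministic
   among cost-equal optima. The step set, metric, and tie rules are
   package choices; the symmetric basic pattern is the least-assuming
   default.

4. **Boundary transfer.** Each reference boundary time b is quantized to
   its frame r = round((b − window/2)/hop), clamped to the frame range;
   the target frames paired with r on the path are collected and the
   upper median taken (robust to the many-to-one plateaus DTW produces in
   pauses; the upper median keeps plateau mappings within one hop of a
   uniform-stretch truth). Boundaries landing on the first or last
   reference frame instead take the first/last paired target frame: the
   DTW endpoint constraint anchors (0,0) and (R−1,T−1), and a plateau
   median there would bias the recording's opening and closing boundaries
   inward. The sub-frame residual b − center(r) is added back after
   mapping, so an identity warp reproduces boundaries exactly.
   Results are clipped to [0, target duration]; an interval collapsing to
   zero length raises a pathological-warp error rather than emitting a
   degenerate parse.

## Evaluation layer

* WER uses unit-cost word edit distance; ties in the (S, D, I)
  decomposition prefer substitution over deletion over insertion.
* IoU with matching counts pairs intervals index-to-index; with
  mismatching counts a greedy descending-IoU matching without reuse is
  used, unmatched intervals score 0, and the mean is over
  max(#pred, #true) — penalizing both over- and under-segmentation.
* CCA is the percentage of recordings with an exactly correct count.
* Bootstrap test sets fix the composition at 5 recordings each from the
  four large diagnostic groups (HC, ALS, PD, PS) plus every member of the
  two smallest (KD, PLS): 24 recordings per set from a 68-recording
  cohort, a 65:35 train:test split. "Sampling with replacement" is
  interpreted as across sets (a recording may recur in different sets);
  each set's category draw is without internal duplicates, since each set
  also includes all KD/PLS files. The within-set interpretation is
  configurable in principle but not exposed as an option.
* One-way ANOVA is the classical F = MS_between/MS_within with df
  (k−1, N−k) (scipy); Tukey HSD uses the Tukey–Kramer CI
  diff ± q(1−α, k, N−k)·√(MS_within/2·(1/n_a+1/n_b)) at α = 0.05, a pair
  being significant iff its CI excludes 0. Report tables use the sample
  (n−1) SD, conventional for small clinical groups.

## Synthetic data

The generator emulates the elicitation protocol for repeated-phrase
recordings: per synthetic speaker, one recording per condition — normal
(rate 1, 0 dB), fast (rate 2), slow (rate 0.5), loud (rate 1, +6 dB) —
each with 4–6 repetitions separated by ~0.3 s pauses. The "loud"
instruction has no canonical gain; +6 dB (one doubling) is the package's
choice. A phrase token is four syllable-like bursts: a harmonic stack on
the speaker's f0 (drawn once per speaker from 100–220 Hz), extending to
~0.45 × the sample rate so every formant region is excited regardless of
f0, weighted by a Gaussian formant-like envelope centered on per-syllable
targets (550/950/1500/2300 Hz, jittered ±5% per speaker), under a
Hann^0.5 amplitude envelope. Token and pause durations jitter ±10% per repetition
so DTW is non-trivial; rate conditions scale durations only, never
frequencies, as human rate changes do. Default additive noise sits at
40 dB SNR (a quiet-room floor); ground-truth intervals bracket the token
spans exactly.

Reference banks for synthetic experiments are built from a designated
held-out synthetic speaker, mirroring the held-out healthy-control
reference of clinical practice.

What the generator does **not** emulate: articulatory detail, consonant
noise, room acoustics, channel effects, or any specific dysarthria
subtype (spastic, flaccid, hypokinetic). Passing synthetic tests
demonstrates the counting, alignment, transfer, and evaluation machinery
— not clinical ASR accuracy, which depends on the transcriber plugged in.

## Numerical choices and degenerate inputs

* Intervals are half-open [onset, offset) seconds; sample index =
  round(t·rate). WAV I/O is 16-bit PCM on write (symmetric ±32768
  scaling), any PCM/float depth on read; multi-channel audio averages to
  mono. All-zero signals are rejected by peak normalization with a
  distinct error.
* The DTW accumulation is JIT-compiled (numba) with an identical
  pure-numpy fallback; both paths are exercised by the same public
  function and checked against exhaustive path enumeration.
* Frame/time conversion uses frame centers; the boundary-transfer error
  budget is one hop plus half a window (22.5 ms at the defaults).
* Uniform-stretch experiments re-render the reference speaker at a scaled
  rate with scaled pauses (same seeds), whose annotation is analytically
  the scaled original to < 0.1 ms; band-limited waveform interpolation
  (`time_stretch`) is provided for duration arithmetic but shifts pitch
  by 1/factor, which no human rate change does, and is therefore not used
  as alignment ground truth.

## Problem sizes

Default experiment sizes are chosen to match the elicitation protocol and
keep everything desk-scale: 20-recording corpora (5 speakers × 4
conditions), 13-entry banks from a 10-repetition source, 200 random
matrices (≤ 6×6) for the DTW oracle, stretch factors {0.5, 0.75, 1.5, 2}
over entries with 2/5/9 repetitions. A full simulate → bank → segment →
evaluate pass runs in seconds on one CPU.

## Known limitations

* The counting threshold (0.5) trades missed repetitions against false
  merges; heavily corrupted transcripts (≥ 2 deletions in one
  repetition) can still miscount.
* Boundary transfer inherits the reference's boundary semantics; if the
  reference parse excludes lead-in breaths, so will the prediction.
* Single-speaker banks only: cross-speaker alignment relies on the
  shared phrase structure and pause anchoring, and degrades gracefully
  (not catastrophically) with voice mismatch.
* DTW is O(R·T) in time and memory; recordings much longer than ~1 min
  at 10 ms hop should use the band option.
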