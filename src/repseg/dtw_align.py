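"""DTW alignment of MFCC sequences and boundary transfer.

The aligner is the classical symmetric dynamic-programming recurrence with
the step set {(1,0), (0,1), (1,1)} and unit weights, no global band by
default (an optional Sakoe-Chiba band is available for speed).  Backtracking
tie-breaks prefer the diagonal step, then the reference-advancing step, so
paths are deterministic.

Known repetition boundaries on the reference timeline are transferred to
the target by converting each boundary time to its reference frame, taking
the median target frame paired with it on the warping path (robust to the
many-to-one plateaus DTW produces inside pauses), and mapping that frame
back to seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .audio_io import AudioSignal, ParseAnnotation, RepetitionInterval, peak_normalize, resample
from .errors import PathologicalWarpError
from .features import (
    MFCCConfig,
    MFCCMatrix,
    compute_mfcc,
    frame_to_time,
    time_to_frame,
    znormalize,
)
from .reference_bank import ReferenceBank, select_reference

__all__ = [
    "WarpingPath",
    "AlignmentResult",
    "frame_distance_matrix",
    "dtw",
    "transfer_boundaries",
    "segment_target",
]

try:  # JIT the O(R*T) accumulation when numba is importable
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


@dataclass(frozen=True)
class WarpingPath:
    """Monotone (ref_frame, target_frame) pairs from (0,0) to (R-1, T-1)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        if not pairs or pairs[0] != (0, 0):
            raise ValueError("warping path must start at (0, 0)")
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            if (i1 - i0, j1 - j0) not in {(1, 0), (0, 1), (1, 1)}:
                raise ValueError(
                    f"invalid path step ({i0},{j0}) -> ({i1},{j1})"
                )
        object.__setattr__(self, "pairs", pairs)

    @property
    def ref_extent(self) -> int:
        return self.pairs[-1][0] + 1

    @property
    def target_extent(self) -> int:
        return self.pairs[-1][1] + 1


@dataclass(frozen=True)
class AlignmentResult:
    path: WarpingPath
    total_cost: float


def frame_distance_matrix(ref: MFCCMatrix, target: MFCCMatrix) -> np.ndarray:
    """Pairwise Euclidean distances between frames, shape (R, T)."""
    if ref.n_coefficients != target.n_coefficients:
        raise ValueError(
            f"coefficient-count mismatch: {ref.n_coefficients} vs "
            f"{target.n_coefficients}"
        )
    if ref.n_frames == 0 or target.n_frames == 0:
        raise ValueError("distance matrix requires non-empty feature matrices")
    return cdist(ref.values, target.values, metric="euclidean")


def _accumulate_py(costs: np.ndarray, band: int) -> np.ndarray:
    n, m = costs.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = costs[0, 0]
    for i in range(n):
        lo = 0 if band < 0 else max(0, i * m // n - band)
        hi = m if band < 0 else min(m, i * m // n + band + 1)
        for j in range(lo, hi):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            if i > 0 and acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if j > 0 and acc[i, j - 1] < best:
                best = acc[i, j - 1]
            if best < np.inf:
                acc[i, j] = costs[i, j] + best
    return acc


if njit is not None:
    _accumulate = njit(cache=True)(_accumulate_py)
else:  # pragma: no cover
    _accumulate = _accumulate_py


def dtw(costs: np.ndarray, band: int | None = None) -> AlignmentResult:
    """Minimum-cost monotone alignment through a local cost matrix.

    Parameters
    ----------
    costs
        (R, T) matrix of non-negative finite local distances.
    band
        Optional Sakoe-Chiba band half-width in frames around the
        resampled diagonal; ``None`` means unconstrained.

    Backtracking prefers diagonal, then reference-advancing steps, so the
    returned path is deterministic among cost-equal optima.
    """
    costs = np.asarray(costs, dtype=np.float64)
    if costs.ndim != 2 or costs.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(costs)) or np.any(costs < 0):
        raise ValueError("cost matrix entries must be finite and non-negative")
    acc = _accumulate(costs, -1 if band is None else int(band))
    n, m = costs.shape
    if not np.isfinite(acc[n - 1, m - 1]):
        raise ValueError("no feasible path within the requested band")
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        # predecessors ranked by accumulated cost, ties by preference order
        candidates: list[tuple[float, int, tuple[int, int]]] = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        path.append((i, j))
    path.reverse()
    return AlignmentResult(path=WarpingPath(pairs=tuple(path)),
                           total_cost=float(acc[n - 1, m - 1]))


def transfer_boundaries(path: WarpingPath, reference_parse: ParseAnnotation,
                        hop_s: float, window_s: float,
                        target_duration_s: float) -> ParseAnnotation:
    """Map each reference onset/offset through the warping path.

    For a boundary at time ``b``: quantize to its reference frame, collect
    the target frames paired with that frame on the path, take the (upper)
    median — or, on the first/last reference frame, the path-anchored
    endpoint — convert back to seconds carrying b's sub-frame residual (so
    an identity warp reproduces b exactly), and clip to
    [0, target_duration].
    A transferred interval collapsing to zero length raises
    :class:`PathologicalWarpError`.
    """
    n_ref = path.ref_extent
    targets_for_ref: dict[int, list[int]] = {}
    for r, t in path.pairs:
        targets_for_ref.setdefault(r, []).append(t)

    # times up to the end of the last analysis window belong to the last frame
    ref_timeline_end = (n_ref - 1) * hop_s + window_s

    def map_time(b: float) -> float:
        if b > ref_timeline_end + hop_s:
            raise ValueError(
                f"reference boundary {b:.3f}s beyond the reference timeline "
                f"({ref_timeline_end:.3f}s for {n_ref} frames)"
            )
        r = time_to_frame(b, hop_s, window_s, n_frames=n_ref)
        frames = targets_for_ref[r]  # arrive sorted by path order
        if r == 0:
            # endpoints are anchored by the path constraint (0,0)/(R-1,T-1);
            # a plateau median would bias them inward
            median = frames[0]
        elif r == n_ref - 1:
            median = frames[-1]
        else:
            median = frames[len(frames) // 2]  # upper median of the plateau
        # carry the sub-frame residual of b so an identity warp is exact
        residual = b - frame_to_time(r, hop_s, window_s)
        t = frame_to_time(median, hop_s, window_s) + residual
        return min(max(t, 0.0), target_duration_s)

    intervals = []
    for k, iv in enumerate(reference_parse.intervals, start=1):
        onset, offset = map_time(iv.onset_s), map_time(iv.offset_s)
        if offset <= onset:
            raise PathologicalWarpError(
                f"repetition {k} collapsed to zero length at "
                f"[{onset:.3f}, {offset:.3f})"
            )
        intervals.append(RepetitionInterval(onset, offset))
    return ParseAnnotation(
        recording_id=f"{reference_parse.recording_id}->target",
        intervals=tuple(intervals),
    )


def segment_target(target: AudioSignal, bank: ReferenceBank, count: int,
                   mfcc_config: MFCCConfig | None = None,
                   band: int | None = None) -> ParseAnnotation:
    """End-to-end segmentation of one recording given its repetition count.

    Peak-normalizes the target, computes z-normalized MFCCs for the target
    and the count-matched reference, aligns them with DTW, and transfers
    the reference's known repetition boundaries onto the target timeline.
    """
    config = mfcc_config or MFCCConfig()
    ref_audio, ref_parse = select_reference(bank, count)

    def features(sig: AudioSignal) -> MFCCMatrix:
        sig = resample(sig, config.sample_rate)
        sig = peak_normalize(sig)
        return znormalize(compute_mfcc(sig, config))

    ref_mfcc, tgt_mfcc = features(ref_audio), features(target)
    result = dtw(frame_distance_matrix(ref_mfcc, tgt_mfcc), band=band)
    predicted = transfer_boundaries(result.path, ref_parse, config.hop_s,
                                    config.window_s, target.duration_s)
    return ParseAnnotation(recording_id="predicted", intervals=predicted.intervals)
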