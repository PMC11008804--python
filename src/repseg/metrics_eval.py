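"""Evaluation metrics, bootstrap test-set construction, ANOVA and Tukey HSD.

Three metrics score a segmentation run, mirroring standard practice for
repeated-phrase parsing tasks:

* WER — word error rate of the transcript against the reference text;
* CCA — correct count accuracy, the percentage of recordings whose
  predicted repetition count equals the annotated count;
* IoU — per-repetition intersection-over-union between predicted and
  annotated intervals, averaged per recording.

Test sets are drawn by bootstrap resampling with a fixed per-category
composition (5 recordings each from the four large diagnostic groups plus
every member of the two smallest), and metric differences across
conditions are assessed with a one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import ParseAnnotation, RepetitionInterval

__all__ = [
    "FileScore",
    "EvaluationReport",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "BootstrapSplit",
    "interval_iou",
    "score_parse",
    "correct_count_accuracy",
    "build_bootstrap_test_sets",
    "one_way_anova",
    "tukey_hsd",
    "make_report",
]

#: Categories sampled 5-at-a-time into each bootstrap test set ...
SAMPLED_CATEGORIES = ("HC", "ALS", "PD", "PS")
#: ... and categories included in full.
FULL_CATEGORIES = ("KD", "PLS")
SAMPLES_PER_CATEGORY = 5


@dataclass(frozen=True)
class FileScore:
    recording_id: str
    category: str
    wer_percent: float
    count_correct: bool
    mean_iou: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_iou <= 1.0):
            raise ValueError(f"mean_iou {self.mean_iou} outside [0, 1]")
        if self.wer_percent < 0:
            raise ValueError(f"negative WER {self.wer_percent}")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-file scores plus per-category and overall aggregates."""

    scores: tuple[FileScore, ...]
    aggregates: pd.DataFrame  # columns: group, metric, mean, sd, n


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]
    alpha: float


@dataclass(frozen=True)
class BootstrapSplit:
    """One bootstrap draw: a test roster and its complement training pool."""

    test: tuple[tuple[str, str], ...]   # (recording_id, category)
    train: tuple[tuple[str, str], ...]


def interval_iou(a: RepetitionInterval, b: RepetitionInterval) -> float:
    """Intersection-over-union of two time intervals; 0 when disjoint."""
    inter = min(a.offset_s, b.offset_s) - max(a.onset_s, b.onset_s)
    if inter <= 0:
        return 0.0
    union = max(a.offset_s, b.offset_s) - min(a.onset_s, b.onset_s)
    return inter / union


def score_parse(predicted: ParseAnnotation, truth: ParseAnnotation) -> float:
    """Mean per-repetition IoU of a predicted parse against ground truth.

    Matching counts pair index-to-index.  Mismatching counts are matched
    greedily by descending IoU without reuse; unmatched intervals score 0
    and the mean is taken over max(#predicted, #true), penalizing both
    over- and under-segmentation.
    """
    if truth.count == 0:
        raise ValueError("ground-truth parse must be non-empty")
    if predicted.count == truth.count:
        ious = [interval_iou(p, t)
                for p, t in zip(predicted.intervals, truth.intervals)]
        return float(np.mean(ious))
    candidates = sorted(
        ((interval_iou(p, t), i, j)
         for i, p in enumerate(predicted.intervals)
         for j, t in enumerate(truth.intervals)),
        key=lambda rec: (-rec[0], rec[1], rec[2]),
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    total = 0.0
    for iou, i, j in candidates:
        if iou <= 0 or i in used_p or j in used_t:
            continue
        total += iou
        used_p.add(i)
        used_t.add(j)
    return total / max(predicted.count, truth.count)


def correct_count_accuracy(pairs: list[tuple[int, int]]) -> float:
    """Percentage of (predicted, true) count pairs that match exactly."""
    if not pairs:
        raise ValueError("correct count accuracy of an empty set is undefined")
    hits = sum(1 for pred, true in pairs if pred == true)
    return 100.0 * hits / len(pairs)


def build_bootstrap_test_sets(roster: list[tuple[str, str]], n_sets: int = 3,
                              seed: int = 0) -> list[BootstrapSplit]:
    """Draw ``n_sets`` composition-fixed bootstrap test sets.

    Each set takes 5 distinct recordings from each of HC/ALS/PD/PS (drawn
    independently per set, so a recording may recur across sets — the
    "with replacement" in the resampling happens at the set level) plus
    every KD and PLS recording.  The complement of each test set is its
    training pool.
    """
    rng = np.random.default_rng(seed)
    by_category: dict[str, list[tuple[str, str]]] = {}
    for rec_id, cat in roster:
        by_category.setdefault(cat, []).append((rec_id, cat))
    for cat in SAMPLED_CATEGORIES:
        if len(by_category.get(cat, [])) < SAMPLES_PER_CATEGORY:
            raise ValueError(
                f"category {cat} has {len(by_category.get(cat, []))} members; "
                f"need >= {SAMPLES_PER_CATEGORY}"
            )
    splits = []
    for _ in range(n_sets):
        test: list[tuple[str, str]] = []
        for cat in SAMPLED_CATEGORIES:
            members = by_category[cat]
            chosen = rng.choice(len(members), size=SAMPLES_PER_CATEGORY,
                                replace=False)
            test.extend(members[i] for i in sorted(chosen))
        for cat in FULL_CATEGORIES:
            test.extend(by_category.get(cat, []))
        test_ids = {rec_id for rec_id, _ in test}
        train = tuple(entry for entry in roster if entry[0] not in test_ids)
        splits.append(BootstrapSplit(test=tuple(test), train=train))
    return splits


def one_way_anova(groups: list[list[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    n_total = sum(len(a) for a in arrays)
    if all(a.std() == 0 for a in arrays):
        raise ValueError("degenerate input: zero within-group variance")
    f_value, p_value = stats.f_oneway(*arrays)
    return AnovaResult(
        f_value=float(f_value), p_value=float(p_value),
        df_between=len(arrays) - 1, df_within=n_total - len(arrays),
    )


def tukey_hsd(groups: dict[str, list[float]], alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey(-Kramer) HSD comparisons at family-wise level alpha.

    CIs are ``diff +/- q(1-alpha, k, N-k) * sqrt(MS_within/2 * (1/n_a + 1/n_b))``;
    a pair is significant exactly when its CI excludes 0.
    """
    labels = list(groups)
    if len(labels) < 2 or any(len(groups[lab]) < 2 for lab in labels):
        raise ValueError("Tukey HSD requires >= 2 groups with >= 2 values each")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if all(a.std() == 0 for a in arrays):
        raise ValueError("degenerate input: zero within-group variance")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append(TukeyPair(
                group_a=labels[i], group_b=labels[j],
                mean_difference=float(res.statistic[i, j]),
                ci_low=float(ci.low[i, j]), ci_high=float(ci.high[i, j]),
            ))
    return TukeyResult(pairs=tuple(pairs), alpha=alpha)


def make_report(scores: list[FileScore]) -> EvaluationReport:
    """Aggregate per-file scores into per-category and overall tables.

    Means with sample (n-1) standard deviations for WER and IoU; CCA as a
    percentage per group.  Categories with no files simply produce no row.
    """
    if not scores:
        raise ValueError("cannot build a report from zero scores")
    df = pd.DataFrame(
        {
            "recording_id": [s.recording_id for s in scores],
            "category": [s.category for s in scores],
            "wer_percent": [s.wer_percent for s in scores],
            "count_correct": [s.count_correct for s in scores],
            "mean_iou": [s.mean_iou for s in scores],
        }
    )
    rows = []
    groups = [("overall", df)] + [
        (cat, sub) for cat, sub in df.groupby("category", sort=True)
    ]
    for name, sub in groups:
        n = len(sub)
        sd = sub[["wer_percent", "mean_iou"]].std(ddof=1).fillna(0.0)
        rows.append((name, "wer_percent", sub["wer_percent"].mean(),
                     sd["wer_percent"], n))
        rows.append((name, "mean_iou", sub["mean_iou"].mean(),
                     sd["mean_iou"], n))
        rows.append((name, "cca_percent",
                     100.0 * sub["count_correct"].mean(), 0.0, n))
    aggregates = pd.DataFrame(rows, columns=["group", "metric", "mean", "sd", "n"])
    return EvaluationReport(scores=tuple(scores), aggregates=aggregates)
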