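"""Metrics, bootstrap test sets, ANOVA and Tukey HSD against formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repseg.audio_io import ParseAnnotation, RepetitionInterval
from repseg.metrics_eval import (
    FileScore,
    build_bootstrap_test_sets,
    correct_count_accuracy,
    interval_iou,
    make_report,
    one_way_anova,
    score_parse,
    tukey_hsd,
)


def anova_oracle(groups):
    """By-hand sums-of-squares decomposition (independent of scipy)."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(all_values) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def tukey_ci_oracle(groups, alpha=0.05):
    """Direct Tukey-Kramer CI per pair via the studentized range quantile."""
    arrays = [np.asarray(g, float) for g in groups.values()]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    ms_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / (n_total - k)
    q = stats.studentized_range.ppf(1 - alpha, k, n_total - k)
    out = {}
    labels = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i].mean() - arrays[j].mean()
            half = q * np.sqrt(ms_within / 2
                               * (1 / len(arrays[i]) + 1 / len(arrays[j])))
            out[(labels[i], labels[j])] = (diff, diff - half, diff + half)
    return out


def iv(a, b):
    return RepetitionInterval(a, b)


def parse(*bounds):
    return ParseAnnotation("p", tuple(iv(a, b) for a, b in bounds))


class TestIntervalIou:
    def test_identical_is_one(self):
        assert interval_iou(iv(1.0, 2.5), iv(1.0, 2.5)) == 1.0

    def test_disjoint_is_zero(self):
        assert interval_iou(iv(0.0, 1.0), iv(2.0, 3.0)) == 0.0

    def test_half_overlap_analytic(self):
        assert interval_iou(iv(0.0, 2.0), iv(1.0, 3.0)) == pytest.approx(1 / 3)

    @given(st.tuples(*[st.integers(0, 500) for _ in range(4)]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, vals):
        # 0.1 s grid keeps "IoU == 1 iff identical" clear of float dust
        a0, a1, b0, b1 = (v / 10.0 for v in vals)
        if not (a0 < a1 and b0 < b1):
            return
        a, b = iv(a0, a1), iv(b0, b1)
        assert interval_iou(a, b) == interval_iou(b, a)
        assert 0.0 <= interval_iou(a, b) <= 1.0
        assert (interval_iou(a, b) == 1.0) == (a == b)


class TestScoreParse:
    def test_identical_parses_score_one(self):
        truth = parse((0, 1), (1.5, 2.5), (3, 4))
        assert score_parse(truth, truth) == 1.0

    def test_one_hit_one_miss_halves(self):
        truth = parse((0, 1), (2, 3))
        predicted = parse((0, 1), (5, 6))
        assert score_parse(predicted, truth) == pytest.approx(0.5)

    def test_count_mismatch_greedy_matching(self):
        # overlaps 0.8 and 0.6 on distinct true intervals, third unmatched
        truth = parse((0.0, 1.0), (2.0, 3.0), (4.0, 5.0))
        predicted = parse((0.0, 1.25), (2.25, 3.25))
        assert interval_iou(predicted.intervals[0],
                            truth.intervals[0]) == pytest.approx(0.8)
        assert interval_iou(predicted.intervals[1],
                            truth.intervals[1]) == pytest.approx(0.6)
        assert score_parse(predicted, truth) == pytest.approx((0.8 + 0.6) / 3)

    def test_never_exceeds_one_and_one_iff_exact(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 6))
            onsets = np.cumsum(rng.uniform(0.5, 1.5, k))
            truth = parse(*[(o, o + 0.4) for o in onsets])
            jitter = rng.uniform(-0.05, 0.05, k)
            predicted = parse(*[(o + d, o + 0.4 + d)
                                for o, d in zip(onsets, jitter)])
            s = score_parse(predicted, truth)
            assert s <= 1.0
            if np.all(jitter == 0):
                assert s == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            score_parse(parse((0, 1)), ParseAnnotation("t", ()))


class TestCorrectCountAccuracy:
    @pytest.mark.parametrize("pairs,expected", [
        ([(5, 5), (7, 7)], 100.0),
        ([(10, 10), (9, 10)], 50.0),
        ([(1, 1)] * 17 + [(2, 1)], pytest.approx(94.44, abs=0.01)),
    ])
    def test_examples(self, pairs, expected):
        assert correct_count_accuracy(pairs) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correct_count_accuracy([])


def cohort_roster():
    """Category composition of the clinical cohort the sampling rule assumes."""
    sizes = {"HC": 27, "ALS": 13, "PD": 11, "PS": 13, "PLS": 2, "KD": 2}
    return [(f"{cat.lower()}{i:02d}", cat)
            for cat, n in sizes.items() for i in range(n)]


class TestBootstrapTestSets:
    def test_three_sets_of_24(self):
        splits = build_bootstrap_test_sets(cohort_roster(), n_sets=3, seed=5)
        assert len(splits) == 3
        assert all(len(s.test) == 24 for s in splits)

    def test_composition_is_5_5_5_5_2_2(self):
        for split in build_bootstrap_test_sets(cohort_roster(), 3, seed=2):
            counts = {}
            for _, cat in split.test:
                counts[cat] = counts.get(cat, 0) + 1
            assert counts == {"HC": 5, "ALS": 5, "PD": 5, "PS": 5,
                              "KD": 2, "PLS": 2}

    def test_no_duplicates_within_a_set(self):
        for split in build_bootstrap_test_sets(cohort_roster(), 5, seed=9):
            ids = [rec_id for rec_id, _ in split.test]
            assert len(ids) == len(set(ids))

    def test_train_pool_is_complement(self):
        roster = cohort_roster()
        for split in build_bootstrap_test_sets(roster, 3, seed=4):
            test_ids = {r for r, _ in split.test}
            train_ids = {r for r, _ in split.train}
            assert test_ids.isdisjoint(train_ids)
            assert test_ids | train_ids == {r for r, _ in roster}

    def test_same_seed_reproducible(self):
        a = build_bootstrap_test_sets(cohort_roster(), 3, seed=7)
        b = build_bootstrap_test_sets(cohort_roster(), 3, seed=7)
        assert [s.test for s in a] == [s.test for s in b]

    def test_insufficient_category_rejected(self):
        roster = [(f"h{i}", "HC") for i in range(4)] \
            + [(f"a{i}", "ALS") for i in range(6)] \
            + [(f"p{i}", "PD") for i in range(6)] \
            + [(f"s{i}", "PS") for i in range(6)]
        with pytest.raises(ValueError):
            build_bootstrap_test_sets(roster, 1, seed=0)


class TestOneWayAnova:
    def test_hand_computed_f(self):
        # SSB = 1.5, SSW = 4 -> F = 1.5 with df (1, 4)
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.f_value == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f_value == pytest.approx(0.0)

    def test_separated_tight_groups_tiny_p(self):
        res = one_way_anova([[0, 0.001, -0.001], [100, 100.001, 99.999]])
        assert res.p_value < 1e-6

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [list(rng.normal(m, 1.5, n))
                  for m, n in [(0, 8), (0.5, 6), (1.2, 9)]]
        res = one_way_anova(groups)
        assert res.f_value == pytest.approx(anova_oracle(groups))

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = list(rng.normal(0, 1, 10)), list(rng.normal(0.7, 1, 12))
        res = one_way_anova([a, b])
        t_stat, _ = stats.ttest_ind(a, b)
        assert res.f_value == pytest.approx(t_stat**2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 1, 1], [2, 2, 2]])


class TestTukeyHsd:
    def test_identical_groups_nothing_significant(self):
        res = tukey_hsd({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert all(not p.significant for p in res.pairs)
        assert all(p.ci_low <= 0 <= p.ci_high for p in res.pairs)

    def test_separated_groups_significant(self):
        res = tukey_hsd({"lo": [0, 0.001, -0.001], "hi": [100, 100.001, 99.999]})
        assert res.pairs[0].significant

    def test_cis_match_studentized_range_oracle(self):
        groups = {
            "a": [10.1, 9.8, 10.4, 10.0, 9.9],
            "b": [11.2, 11.0, 11.5, 10.8, 11.1],
            "c": [10.5, 10.2, 10.9, 10.4, 10.6],
        }
        res = tukey_hsd(groups, alpha=0.05)
        oracle = tukey_ci_oracle(groups, alpha=0.05)
        for pair in res.pairs:
            diff, lo, hi = oracle[(pair.group_a, pair.group_b)]
            assert pair.mean_difference == pytest.approx(diff)
            assert pair.ci_low == pytest.approx(lo, abs=1e-6)
            assert pair.ci_high == pytest.approx(hi, abs=1e-6)

    def test_significance_iff_ci_excludes_zero(self, rng):
        groups = {c: list(rng.normal(i * 0.8, 1, 6))
                  for i, c in enumerate("abcd")}
        for pair in tukey_hsd(groups).pairs:
            assert pair.significant == (not pair.ci_low <= 0 <= pair.ci_high)

    def test_significance_monotone_in_effect_size(self, rng):
        base = {c: list(rng.normal(i, 1, 6)) for i, c in enumerate("abc")}
        sig_before = {(p.group_a, p.group_b)
                      for p in tukey_hsd(base).pairs if p.significant}
        spread = {c: [v + i * 5 for v in g]
                  for i, (c, g) in enumerate(base.items())}
        sig_after = {(p.group_a, p.group_b)
                     for p in tukey_hsd(spread).pairs if p.significant}
        assert sig_before <= sig_after


class TestMakeReport:
    def _score(self, rid, cat, wer, correct, iou):
        return FileScore(recording_id=rid, category=cat, wer_percent=wer,
                         count_correct=correct, mean_iou=iou)

    def test_single_file_aggregates_equal_values(self):
        report = make_report([self._score("r1", "HC", 12.5, True, 0.85)])
        agg = report.aggregates.set_index(["group", "metric"])
        assert agg.loc[("overall", "wer_percent"), "mean"] == 12.5
        assert agg.loc[("overall", "wer_percent"), "sd"] == 0.0
        assert agg.loc[("HC", "cca_percent"), "mean"] == 100.0

    def test_two_files_mean_and_sample_sd(self):
        report = make_report([
            self._score("r1", "HC", 0.0, True, 0.8),
            self._score("r2", "HC", 0.0, False, 1.0),
        ])
        agg = report.aggregates.set_index(["group", "metric"])
        assert agg.loc[("overall", "mean_iou"), "mean"] == pytest.approx(0.9)
        assert agg.loc[("overall", "mean_iou"), "sd"] == pytest.approx(
            np.std([0.8, 1.0], ddof=1))
        assert agg.loc[("overall", "cca_percent"), "mean"] == 50.0

    def test_absent_category_produces_no_row(self):
        report = make_report([self._score("r1", "HC", 1.0, True, 0.9)])
        assert "ALS" not in set(report.aggregates["group"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_report([])
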