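"""Beat matching, score aggregation, KS test, synchronization, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarvitals.evaluation import (
    align_by_sync,
    cohort_summary,
    exclude_outliers,
    ks_two_sample,
    load_table1,
    load_table2,
    match_beats,
    matched_ibi_pairs,
    scores_from_counts,
    table2_subject_scores,
)
from radarvitals.heartbeat import BeatTimes


def bt(times, source="heart_sound"):
    return BeatTimes(times=np.asarray(times, float), source=source)


class TestMatchBeats:
    def test_hand_matched_example(self):
        m = match_beats(bt([10.05, 11.10, 12.02]), bt([10.00, 11.00, 12.00]))
        assert (m.tp, m.fp, m.fn) == (2, 1, 1)
        assert m.pairs == [(10.00, 10.05), (12.00, 12.02)]

    def test_identical_lists_all_tp(self):
        m = match_beats(bt([1.0, 2.0, 3.0]), bt([1.0, 2.0, 3.0]))
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_one_to_one_double_prediction(self):
        m = match_beats(bt([9.98, 10.03]), bt([10.0]))
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs == [(10.0, 9.98)]  # the closer one wins

    def test_closed_tolerance_interval(self):
        m = match_beats(bt([10.075]), bt([10.0]))
        assert m.tp == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted|increasing"):
            match_beats(bt([2.0, 1.0]), bt([1.0]))

    @given(
        ref=st.lists(st.floats(0, 100), min_size=0, max_size=30),
        pred=st.lists(st.floats(0, 100), min_size=0, max_size=30),
        tol=st.floats(1.0, 200.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_count_identities_hold(self, ref, pred, tol):
        ref = sorted(set(ref))
        pred = sorted(set(pred))
        m = match_beats(bt(pred), bt(ref), tol)
        assert m.tp + m.fn == len(ref)
        assert m.tp + m.fp == len(pred)
        assert len(set(r for r, _ in m.pairs)) == m.tp
        assert len(set(p for _, p in m.pairs)) == m.tp

    @given(
        ref=st.lists(st.integers(0, 100_000), min_size=1, max_size=20),
        pred=st.lists(st.integers(0, 100_000), min_size=1, max_size=20),
        shift_ms=st.integers(-50_000, 50_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_translation_invariance_and_tolerance_monotonicity(self, ref, pred, shift_ms):
        # millisecond grid keeps times distinct under translation
        ref = [v / 1000.0 for v in sorted(set(ref))]
        pred = [v / 1000.0 for v in sorted(set(pred))]
        shift = shift_ms / 1000.0
        # tolerance off the millisecond grid avoids float boundary flips
        m1 = match_beats(bt(pred), bt(ref), 60.5)
        shifted = match_beats(
            bt([p + shift for p in pred]), bt([r + shift for r in ref]), 60.5
        )
        assert (m1.tp, m1.fp, m1.fn) == (shifted.tp, shifted.fp, shifted.fn)
        wider = match_beats(bt(pred), bt(ref), 120.5)
        assert wider.tp >= m1.tp


class TestScores:
    def test_printed_subject_rows(self):
        precision, recall, f1 = scores_from_counts(691, 30, 29)
        assert f1 == pytest.approx(95.91, abs=0.01)
        assert recall == pytest.approx(95.97, abs=0.01)
        assert precision == pytest.approx(95.84, abs=0.01)
        assert scores_from_counts(593, 0, 0) == pytest.approx((100.0, 100.0, 100.0))

    def test_zero_tp_gives_zero_scores(self):
        assert scores_from_counts(0, 5, 5) == (0.0, 0.0, 0.0)

    def test_undefined_when_denominator_missing(self):
        assert all(np.isnan(scores_from_counts(0, 0, 5)))

    def test_f1_between_precision_and_recall(self):
        scores = table2_subject_scores()
        for s in scores:
            assert min(s.precision, s.sensitivity) - 1e-9 <= s.f1
            assert s.f1 <= max(s.precision, s.sensitivity) + 1e-9


class TestCohort:
    def test_single_subject_micro_equals_macro(self):
        s = table2_subject_scores()[:1]
        summary = cohort_summary(s)
        assert summary.micro_mean["f1"] == pytest.approx(summary.macro["f1"], abs=0.01)

    def test_equal_subjects_macro_matches_each(self):
        s = table2_subject_scores()[3]
        summary = cohort_summary([s, s])
        assert summary.macro["f1"] == pytest.approx(s.f1, abs=0.01)
        assert summary.micro_sd["f1"] == 0.0

    def test_macro_permutation_invariant(self):
        scores = table2_subject_scores()
        a = cohort_summary(scores)
        b = cohort_summary(list(reversed(scores)))
        assert a.macro == b.macro

    def test_exclusion_all_equal_keeps_everything(self):
        s = table2_subject_scores()[0]
        summary, excluded, _ = exclude_outliers([s, s, s])
        assert excluded == []
        assert summary.n_subjects == 3

    def test_single_subject_rule_skipped(self):
        s = table2_subject_scores()[:1]
        summary, excluded, threshold = exclude_outliers(s)
        assert excluded == []
        assert np.isnan(threshold)


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_quarter_shift_oracle(self):
        """D cross-checked against brute-force ECDF enumeration."""
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        grid = sorted(set(a) | set(b))
        ecdf = lambda s, x: sum(v <= x for v in s) / len(s)
        d_oracle = max(abs(ecdf(a, x) - ecdf(b, x)) for x in grid)
        d, p = ks_two_sample(a, b)
        assert d == pytest.approx(d_oracle) == pytest.approx(0.25)
        assert 0.0 < p <= 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])


class TestAlign:
    def test_identical_sequences_zero_lag(self, rng):
        x = rng.standard_normal(2000)
        res = align_by_sync(x, x)
        assert res.lag == 0
        assert res.confident

    def test_constructed_shift_recovered(self, rng):
        x = rng.standard_normal(2000)
        delayed = np.concatenate([np.zeros(37), x[:-37]])
        res = align_by_sync(x, delayed)
        assert abs(res.lag) == 37
        assert res.peak_correlation > 0.95

    def test_independent_noise_flagged_unconfident(self, rng):
        a = rng.standard_normal(4000)
        b = rng.standard_normal(4000)
        res = align_by_sync(a, b)
        assert not res.confident

    def test_rate_mismatch_resampled(self, rng):
        x = np.sin(2 * np.pi * 1.0 * np.arange(1000) / 100.0) + 0.1 * rng.standard_normal(1000)
        x2 = x[::2]  # same signal at 50 Sa/s
        res = align_by_sync(x, x2, rate_a=100.0, rate_b=50.0)
        assert res.common_rate == 100.0
        assert abs(res.lag) <= 2

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            align_by_sync(np.zeros(100), np.ones(100))


class TestMatchedIbi:
    def test_skips_interval_across_missed_beat(self):
        ref = bt([1.0, 2.0, 3.0, 4.0], source="ecg_reference")
        pred = bt([1.01, 3.01, 4.01])  # beat at 2.0 missed
        m = match_beats(pred, ref)
        pred_ibi, ref_ibi = matched_ibi_pairs(m, ref)
        np.testing.assert_allclose(ref_ibi.intervals, [1.0])
        np.testing.assert_allclose(pred_ibi.intervals, [1.0], atol=0.02)


class TestFixtures:
    def test_tables_load_with_expected_shape(self):
        t1, t2 = load_table1(), load_table2()
        assert len(t1) == len(t2) == 30
        assert {"rxy_max", "m_max", "rmse_zc"} <= set(t1.columns)
        assert {"f1", "tp", "fp", "fn"} <= set(t2.columns)

    def test_every_row_recomputes_from_counts(self):
        """Printed per-subject scores agree with their own TP/FP/FN."""
        for s in table2_subject_scores():
            precision, recall, f1 = scores_from_counts(s.tp, s.fp, s.fn)
            assert f1 == pytest.approx(s.f1, abs=0.01)
            assert recall == pytest.approx(s.sensitivity, abs=0.01)
            assert precision == pytest.approx(s.precision, abs=0.01)
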