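"""Scoring, aggregation and alignment utilities.

Beat detections are scored against ECG R-peak references with a ±75 ms
tolerance and one-to-one matching; per-subject precision / recall
(sensitivity) / F1 are aggregated over a cohort either as the arithmetic
mean of per-subject scores ("micro mean", with SD) or by pooling the
TP/FP/FN counts first ("macro mean").  Subjects whose F1 falls more than
two standard deviations below the cohort mean are excluded and the
summary recomputed.  Two estimator populations are compared with the
two-sample Kolmogorov-Smirnov test, and two recordings are aligned by
the cross-correlation of a shared synchronization sequence.

The per-subject result tables of the validation study this package
models ship as CSV fixtures (``radarvitals/data``); ``cohort_summary``
and ``exclude_outliers`` reproduce their printed aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .heartbeat import BeatTimes, IbiSeries

__all__ = [
    "MatchResult",
    "SubjectScores",
    "CohortSummary",
    "AlignResult",
    "match_beats",
    "scores_from_counts",
    "cohort_summary",
    "exclude_outliers",
    "ks_two_sample",
    "align_by_sync",
    "matched_ibi_pairs",
    "load_table1",
    "load_table2",
    "table2_subject_scores",
]

SCORE_COLUMNS = ("f1", "sensitivity", "precision")


@dataclass
class MatchResult:
    """One-to-one beat matching outcome at a given tolerance."""

    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[float, float]]  # (reference time, predicted time)
    tolerance_ms: float


@dataclass
class SubjectScores:
    """Detection scores for one subject, percentages in [0, 100]."""

    subject_id: object
    f1: float
    sensitivity: float
    precision: float
    tp: int
    fp: int
    fn: int
    n_ref_beats: Optional[int] = None
    n_pred_beats: Optional[int] = None
    duration_s: Optional[float] = None


@dataclass
class CohortSummary:
    """Micro (mean of per-subject scores) and macro (pooled counts) means."""

    micro_mean: Dict[str, float]
    micro_sd: Dict[str, float]
    macro: Dict[str, float]
    n_subjects: int
    total_counts: Dict[str, int]


@dataclass
class AlignResult:
    """Lag (in samples of the common rate) aligning two sync sequences."""

    lag: int
    peak_correlation: float
    confident: bool
    common_rate: Optional[float] = None


def match_beats(
    pred: BeatTimes, ref: BeatTimes, tolerance_ms: float = 75.0
) -> MatchResult:
    """Match predicted to reference beats within ±tolerance, one-to-one.

    Greedy closest-first assignment over all candidate pairs sorted by
    absolute time difference: each reference beat takes at most one
    prediction inside the closed ±tolerance interval.  Unmatched
    references count as FN, unmatched predictions as FP.
    """
    p = np.asarray(pred.times, dtype=float)
    r = np.asarray(ref.times, dtype=float)
    for name, arr in (("pred", p), ("ref", r)):
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError(f"{name} beat times must be sorted strictly increasing")
    tol = tolerance_ms / 1000.0
    cands = []
    for i, rt in enumerate(r):
        for j in range(p.size):
            dt = p[j] - rt
            if abs(dt) <= tol:
                cands.append((abs(dt), i, j))
    cands.sort()
    used_r = np.zeros(r.size, dtype=bool)
    used_p = np.zeros(p.size, dtype=bool)
    pairs = []
    for _, i, j in cands:
        if not used_r[i] and not used_p[j]:
            used_r[i] = used_p[j] = True
            pairs.append((float(r[i]), float(p[j])))
    pairs.sort()
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=int(p.size - tp),
        fn=int(r.size - tp),
        pairs=pairs,
        tolerance_ms=tolerance_ms,
    )


def scores_from_counts(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """(precision, recall, F1) in percent from TP/FP/FN counts.

    When both denominators exist but TP is zero, all three scores are 0
    by convention; when a denominator is zero the corresponding scores
    are NaN (undefined).
    """
    if tp + fp == 0 or tp + fn == 0:
        return (np.nan, np.nan, np.nan)
    precision = 100.0 * tp / (tp + fp)
    recall = 100.0 * tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2.0 * precision * recall / (precision + recall)
    return (precision, recall, f1)


def subject_scores_from_match(subject_id, match: MatchResult, **extra) -> SubjectScores:
    precision, recall, f1 = scores_from_counts(match.tp, match.fp, match.fn)
    return SubjectScores(
        subject_id=subject_id,
        f1=f1,
        sensitivity=recall,
        precision=precision,
        tp=match.tp,
        fp=match.fp,
        fn=match.fn,
        **extra,
    )


def cohort_summary(scores: Sequence[SubjectScores]) -> CohortSummary:
    """Micro and macro aggregation of per-subject scores.

    Micro: arithmetic mean and sample SD of each score column.  Macro:
    scores recomputed from the summed TP/FP/FN, hence permutation
    invariant and derivable from the count sums alone.
    """
    if len(scores) == 0:
        raise ValueError("empty cohort")
    cols = {c: np.array([getattr(s, c) for s in scores], dtype=float) for c in SCORE_COLUMNS}
    micro_mean = {c: float(np.mean(v)) for c, v in cols.items()}
    micro_sd = {
        c: float(np.std(v, ddof=1)) if len(scores) > 1 else np.nan for c, v in cols.items()
    }
    tp = int(sum(s.tp for s in scores))
    fp = int(sum(s.fp for s in scores))
    fn = int(sum(s.fn for s in scores))
    precision, recall, f1 = scores_from_counts(tp, fp, fn)
    return CohortSummary(
        micro_mean=micro_mean,
        micro_sd=micro_sd,
        macro={"f1": f1, "sensitivity": recall, "precision": precision},
        n_subjects=len(scores),
        total_counts={"tp": tp, "fp": fp, "fn": fn},
    )


def exclude_outliers(
    scores: Sequence[SubjectScores], k: float = 2.0
) -> Tuple[CohortSummary, List[object], float]:
    """Drop subjects whose F1 lies more than k sample SDs below the mean.

    Returns the recomputed summary on the remaining subjects, the
    excluded subject ids, and the threshold (mean F1 − k·SD).  With a
    single subject the SD is undefined and the rule is skipped.
    """
    if len(scores) < 2:
        return cohort_summary(scores), [], np.nan
    f1 = np.array([s.f1 for s in scores], dtype=float)
    threshold = float(np.mean(f1) - k * np.std(f1, ddof=1))
    keep = [s for s in scores if s.f1 >= threshold]
    excluded = [s.subject_id for s in scores if s.f1 < threshold]
    return cohort_summary(keep), excluded, threshold


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def align_by_sync(
    sync_a: np.ndarray,
    sync_b: np.ndarray,
    rate_a: Optional[float] = None,
    rate_b: Optional[float] = None,
    confidence_threshold: float = 0.5,
) -> AlignResult:
    """Signed lag of the normalized cross-correlation maximum.

    Both devices record the same synchronization noise sequence; the lag
    that maximizes their normalized cross-correlation aligns the two
    recordings.  When the rates differ, both sequences are first
    resampled to the higher one.  A peak correlation below the
    confidence threshold is flagged.
    """
    a = np.asarray(sync_a, dtype=float)
    b = np.asarray(sync_b, dtype=float)
    common = None
    if rate_a is not None and rate_b is not None and rate_a != rate_b:
        common = max(rate_a, rate_b)
        for which, (x, rx) in enumerate(((a, rate_a), (b, rate_b))):
            frac = Fraction(common / rx).limit_denominator(10000)
            res = sps.resample_poly(x, frac.numerator, frac.denominator)
            if which == 0:
                a = res
            else:
                b = res
    a = a - a.mean()
    b = b - b.mean()
    ea, eb = float(np.sum(a**2)), float(np.sum(b**2))
    if ea == 0.0 or eb == 0.0:
        raise ValueError("zero-energy synchronization sequence")
    corr = sps.correlate(a, b, mode="full") / np.sqrt(ea * eb)
    lags = sps.correlation_lags(a.size, b.size, mode="full")
    i = int(np.argmax(corr))
    peak = float(corr[i])
    return AlignResult(
        lag=int(lags[i]),
        peak_correlation=peak,
        confident=peak >= confidence_threshold,
        common_rate=common,
    )


def matched_ibi_pairs(
    match: MatchResult, ref_all: Optional[BeatTimes] = None
) -> Tuple[IbiSeries, IbiSeries]:
    """Paired interbeat intervals over consecutive matched beats.

    Intervals are formed between consecutive matched (reference,
    prediction) pairs.  When the full reference list is supplied, pairs
    separated by an unmatched reference beat are skipped, so a missed
    beat does not create a spurious double-length interval.
    """
    if len(match.pairs) < 2:
        return IbiSeries(intervals=np.array([])), IbiSeries(intervals=np.array([]))
    pairs = sorted(match.pairs)
    ref_t = np.array([r for r, _ in pairs])
    pred_t = np.array([p for _, p in pairs])
    keep = np.ones(len(pairs) - 1, dtype=bool)
    if ref_all is not None:
        full = np.asarray(ref_all.times, dtype=float)
        idx = np.searchsorted(full, ref_t)
        keep = np.diff(idx) == 1
    ref_ibi = np.diff(ref_t)[keep]
    pred_ibi = np.diff(pred_t)[keep]
    return IbiSeries(intervals=pred_ibi), IbiSeries(intervals=ref_ibi)


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("radarvitals.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Per-subject respiration results of the reference validation study."""
    return _read_fixture("table1.csv")


def load_table2() -> pd.DataFrame:
    """Per-subject heartbeat-detection results of the validation study."""
    return _read_fixture("table2.csv")


def table2_subject_scores(df: Optional[pd.DataFrame] = None) -> List[SubjectScores]:
    """Turn the bundled per-subject table into SubjectScores records."""
    if df is None:
        df = load_table2()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SubjectScores(
                subject_id=int(row.id),
                f1=float(row.f1),
                sensitivity=float(row.sensitivity),
                precision=float(row.precision),
                tp=int(row.tp),
                fp=int(row.fp),
                fn=int(row.fn),
                n_ref_beats=int(row.n_rpeaks_ecg),
                n_pred_beats=int(row.n_pred_hb),
                duration_s=float(row.meas_time_s),
            )
        )
    return out
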