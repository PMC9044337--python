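"""Frame-wise and blink-level scoring: confusion, P/R/F1, AUC, matching."""

import itertools

import numpy as np
import pytest

from earblink.annotations import BlinkInterval, GroundTruth
from earblink.errors import DataError, UndefinedAUCError
from earblink.evaluation import (
    ConfusionCounts,
    confusion,
    evaluate,
    match_blinks,
    precision_recall_f1,
    roc_auc,
)
from earblink.events import BlinkEvent
from earblink.geometry import EyeState

from .test_annotations import make_record

O, C, U = EyeState.OPEN, EyeState.CLOSED, EyeState.UNKNOWN


def labels(seq):
    return {i: s for i, s in enumerate(seq)}


class TestConfusion:
    def test_perfect_prediction(self):
        truth = labels([C, C, C, O, O, O, O, O, O, O])
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 7, 0, 0)

    def test_all_open_prediction(self):
        truth = labels([C, C, C] + [O] * 7)
        pred = labels([O] * 10)
        c = confusion(pred, truth)
        assert (c.fn, c.tn, c.tp, c.fp) == (3, 7, 0, 0)

    def test_disjoint_indices_error(self):
        with pytest.raises(DataError):
            confusion({0: O}, {1: O})

    def test_unknown_frames_excluded(self):
        c = confusion(labels([C, U, O]), labels([C, C, U]))
        assert c.total == 1 and c.tp == 1

    def test_matches_bruteforce_tally(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 100))
            pred = labels([[O, C][i] for i in rng.integers(0, 2, size=n)])
            truth = labels([[O, C][i] for i in rng.integers(0, 2, size=n)])
            c = confusion(pred, truth)
            tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
            for i in range(n):
                key = ("t" if pred[i] == truth[i] else "f") + (
                    "p" if pred[i] is C else "n"
                )
                tally[key] += 1
            assert (c.tp, c.fp, c.tn, c.fn) == (
                tally["tp"], tally["fp"], tally["tn"], tally["fn"],
            )
            assert c.total == n  # counting conservation


class TestPrecisionRecallF1:
    def test_direct_formula_example(self):
        m = precision_recall_f1(ConfusionCounts(tp=9, fp=1, tn=0, fn=9))
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.5)
        assert m.f1 == pytest.approx(2 * 0.9 * 0.5 / 1.4, abs=1e-3)

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            m = precision_recall_f1(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert m.precision == 0.0

    def test_matches_independent_evaluation(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            m = precision_recall_f1(ConfusionCounts(tp, fp, tn, fn))
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert m.precision == pytest.approx(p)
            assert m.recall == pytest.approx(r)
            assert m.f1 == pytest.approx(2 * p * r / (p + r))
            assert m.support == tp + fn


def auc_pairwise_oracle(scores, truth):
    """O(n^2) pairwise-comparison AUC, ties counted one half."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [False] * 3 + [True] * 2) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([5.0] * 6, [True, False] * 3) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 50))
            scores = rng.choice([0.1, 0.25, 0.3, 0.7, 0.9], size=n)  # force ties
            truth = rng.integers(0, 2, size=n).astype(bool)
            if truth.all() or not truth.any():
                continue
            assert roc_auc(scores, truth) == pytest.approx(
                auc_pairwise_oracle(scores, truth), abs=1e-12
            )

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        truth = rng.integers(0, 2, size=100).astype(bool)
        base = roc_auc(scores, truth)
        assert roc_auc(np.exp(scores), truth) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * scores + 7, truth) == pytest.approx(base, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=300)
        truth = rng.integers(0, 2, size=300).astype(bool)
        assert roc_auc(scores, truth) == pytest.approx(
            sklearn_metrics.roc_auc_score(truth, scores), abs=1e-12
        )


def event(start, end):
    n = end - start + 1
    return BlinkEvent(start, start + (n - 1) // 2, end, n, n / 30)


def bruteforce_max_matching(detected, truth):
    """Exhaustive maximum one-to-one overlap matching on small inputs."""

    def rec(i, used):
        if i == len(detected):
            return 0
        best = rec(i + 1, used)  # leave detected[i] unmatched
        for j, t in enumerate(truth):
            if j not in used and detected[i].overlaps(t.start_frame, t.end_frame):
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


class TestMatchBlinks:
    def test_identical_lists(self):
        evs = [event(0, 4), event(10, 14), event(30, 33)]
        ivs = [BlinkInterval(i + 1, e.start_frame, e.end_frame) for i, e in enumerate(evs)]
        assert match_blinks(evs, ivs) == (3, 0, 0)

    def test_no_detections(self):
        ivs = [BlinkInterval(1, 0, 3), BlinkInterval(2, 10, 12)]
        assert match_blinks([], ivs) == (0, 0, 2)

    def test_one_frame_overlap_suffices(self):
        assert match_blinks([event(0, 5)], [BlinkInterval(1, 5, 9)]) == (1, 0, 0)
        assert match_blinks([event(0, 5)], [BlinkInterval(1, 6, 9)]) == (0, 1, 1)

    def test_counts_conserve_truth_total(self, rng):
        for _ in range(50):
            det, tru = _random_disjoint(rng), _random_truth(rng)
            tp, fp, fn = match_blinks(det, tru)
            assert tp + fn == len(tru)
            assert tp + fp == len(det)

    def test_matches_exhaustive_optimum_on_small_inputs(self, rng):
        for _ in range(100):
            det, tru = _random_disjoint(rng, max_events=5), _random_truth(rng, max_events=5)
            tp, _, _ = match_blinks(det, tru)
            assert tp == bruteforce_max_matching(det, tru)


def _random_disjoint(rng, max_events=6):
    events = []
    pos = 0
    for _ in range(int(rng.integers(0, max_events + 1))):
        pos += int(rng.integers(1, 8))
        end = pos + int(rng.integers(0, 6))
        events.append(event(pos, end))
        pos = end + 1
    return events


def _random_truth(rng, max_events=6):
    return [
        BlinkInterval(i + 1, e.start_frame, e.end_frame)
        for i, e in enumerate(_random_disjoint(rng, max_events))
    ]


class TestEvaluate:
    def _gt(self, truth_states):
        records = []
        blink = 0
        prev_closed = False
        for i, s in enumerate(truth_states):
            closed = s is C
            if closed and not prev_closed:
                blink += 1
            records.append(make_record(i, blink_id=blink if closed else None,
                                       le_fc="C" if closed else "X",
                                       re_fc="C" if closed else "X"))
            prev_closed = closed
        return GroundTruth(records)

    def test_perfect_prediction_scores(self):
        truth = [O, O, C, C, C, O, O, O, O, O]
        gt = self._gt(truth)
        pred = labels(truth)
        scores = {i: (1.0 if s is C else -1.0) for i, s in enumerate(truth)}
        events = [event(2, 4)]
        rep = evaluate(pred, gt, events=events, scores=scores)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0
        assert rep.per_class["closed"].f1 == 1.0
        assert rep.per_class["open"].f1 == 1.0
        assert (rep.blink_tp, rep.blink_fp, rep.blink_fn) == (1, 0, 0)

    def test_inverted_prediction_on_balanced_labels(self):
        truth = [C, O] * 5
        gt = self._gt(truth)
        pred = labels([O if s is C else C for s in truth])
        rep = evaluate(pred, gt)
        assert rep.accuracy == 0.0

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 60))
            truth = [[O, C][i] for i in rng.integers(0, 2, size=n)]
            pred = labels([[O, C][i] for i in rng.integers(0, 2, size=n)])
            rep = evaluate(pred, self._gt(truth))
            assert rep.weighted_avg.recall == pytest.approx(rep.accuracy, abs=1e-12)
            assert rep.per_class["open"].support + rep.per_class["closed"].support \
                == rep.counts.total

    def test_macro_is_unweighted_mean(self):
        truth = [C, C, O, O, O, O]
        pred = labels([C, O, O, O, C, O])
        rep = evaluate(pred, self._gt(truth))
        assert rep.macro_avg.precision == pytest.approx(
            (rep.per_class["open"].precision + rep.per_class["closed"].precision) / 2
        )

    def test_report_serialization(self, tmp_path):
        truth = [O, C, C, C, O, O]
        rep = evaluate(labels(truth), self._gt(truth), events=[event(1, 3)],
                       scores={i: (1.0 if s is C else 0.0) for i, s in enumerate(truth)},
                       threshold=0.2)
        d = rep.to_dict()
        assert d["confusion"]["tp"] == 3
        text = rep.to_text()
        assert "Eye Closeness Frame by Frame Test Scores" in text
        assert "Macro avg" in text and "Weight avg" in text
        rep.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
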