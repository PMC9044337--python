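"""Frame-wise and blink-level scoring against annotated ground truth.

Frame-wise: confusion counts over the jointly labelled frames (positive class
= closed), precision P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R),
per-class plus macro (unweighted mean) and support-weighted averages, overall
accuracy, and the ROC AUC of a continuous closedness score.  The AUC is the
probability that a random closed frame outranks a random open one (ties count
one half) — the Mann-Whitney statistic — and is therefore invariant under any
strictly increasing transform of the score; the natural score is the negated
EAR, since a lower EAR means a more closed eye.

Blink-level: detected events are matched one-to-one against ground-truth
intervals greedily in start order, a pair matching when the intervals overlap
by at least one frame; unmatched detections are false positives, unmatched
truth intervals false negatives.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotations import BlinkInterval, GroundTruth
from .errors import DataError, UndefinedAUCError
from .events import BlinkEvent
from .geometry import EyeState

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "EvaluationReport",
    "confusion",
    "precision_recall_f1",
    "roc_auc",
    "match_blinks",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is *closed*."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    def swapped(self) -> "ConfusionCounts":
        """Counts with the class roles exchanged (open as positive)."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    """Precision/recall/F1 for one class (or an average) with its support."""

    precision: float
    recall: float
    f1: float
    support: int


def confusion(
    pred: Mapping[int, EyeState], truth: Mapping[int, EyeState]
) -> ConfusionCounts:
    """Tally confusion counts over frames labelled (non-UNKNOWN) on both sides."""
    common = set(pred) & set(truth)
    if not common:
        raise DataError("prediction and truth share no frame indices")
    tp = fp = tn = fn = 0
    for idx in common:
        p, t = pred[idx], truth[idx]
        if p is EyeState.UNKNOWN or t is EyeState.UNKNOWN:
            continue
        if t is EyeState.CLOSED:
            if p is EyeState.CLOSED:
                tp += 1
            else:
                fn += 1
        else:
            if p is EyeState.CLOSED:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(c: ConfusionCounts) -> ClassMetrics:
    """P/R/F1 of the positive class of ``c``; zero denominators yield 0."""
    p = _safe_div(c.tp, c.tp + c.fp, "precision")
    r = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "F1")
    return ClassMetrics(precision=p, recall=r, f1=f1, support=c.tp + c.fn)


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (average ranks => ties = 1/2).

    ``truth`` marks the positive (closed) frames; ``scores`` rank frames by
    closedness (higher = more closed).  Raises :class:`UndefinedAUCError` if
    only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise DataError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = int(truth.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: ground truth has a single class")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def match_blinks(
    detected: Sequence[BlinkEvent],
    truth_intervals: Sequence[BlinkInterval],
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs ground-truth blinks.

    Both lists are taken in start order; a detection matches the earliest
    still-unmatched truth interval it overlaps by >= 1 frame.  Returns
    (blink_tp, blink_fp, blink_fn).
    """
    det = sorted(detected, key=lambda e: e.start_frame)
    tru = sorted(truth_intervals, key=lambda t: t.start_frame)
    matched_truth = [False] * len(tru)
    tp = 0
    j = 0
    for ev in det:
        # skip truth intervals that end before this detection and are settled
        while j < len(tru) and tru[j].end_frame < ev.start_frame:
            j += 1
        k = j
        while k < len(tru) and tru[k].start_frame <= ev.end_frame:
            if not matched_truth[k] and tru[k].overlaps(ev.start_frame, ev.end_frame):
                matched_truth[k] = True
                tp += 1
                break
            k += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    return tp, fp, fn


@dataclass(frozen=True)
class EvaluationReport:
    """Full scoring report: confusion, per-class metrics, averages, AUC, blinks."""

    counts: ConfusionCounts
    per_class: dict  # {"open": ClassMetrics, "closed": ClassMetrics}
    macro_avg: ClassMetrics
    weighted_avg: ClassMetrics
    accuracy: float
    auc: float | None
    blink_tp: int
    blink_fp: int
    blink_fn: int
    prediction_summary: dict | None = None
    test_summary: dict | None = None
    threshold: float | None = None

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "confusion": asdict(self.counts),
            "per_class": {k: asdict(v) for k, v in self.per_class.items()},
            "macro_avg": asdict(self.macro_avg),
            "weighted_avg": asdict(self.weighted_avg),
            "accuracy": self.accuracy,
            "auc": self.auc,
            "blinks": {"tp": self.blink_tp, "fp": self.blink_fp, "fn": self.blink_fn},
        }
        if self.prediction_summary is not None:
            d["prediction_set"] = self.prediction_summary
        if self.test_summary is not None:
            d["test_set"] = self.test_summary
        return d

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        """Plain-text report: prediction/test-set statistics then frame scores."""
        lines: list[str] = []
        if self.threshold is not None:
            lines.append(f"EAR Threshold (t)              {self.threshold:.4f}")
        for title, summ in (
            ("Statistics on the prediction set", self.prediction_summary),
            ("Statistics on the test set", self.test_summary),
        ):
            if summ is None:
                continue
            lines.append(title)
            lines.append(f"  Total Number of Frames Processed  {summ['total_frames_processed']}")
            lines.append(f"  Number of Closed Frames           {summ['n_closed_frames']}")
            lines.append(f"  Number of Blinks                  {summ['n_blinks']}")
        lines.append("Eye Closeness Frame by Frame Test Scores")
        lines.append(f"  Accuracy  {self.accuracy:.4f}")
        if self.auc is not None:
            lines.append(f"  AUC       {self.auc:.4f}")
        lines.append(f"{'':12s}{'Precision':>10s}{'Recall':>10s}{'F1-score':>10s}{'Support':>10s}")
        rows = [
            ("0 (open)", self.per_class["open"]),
            ("1 (closed)", self.per_class["closed"]),
            ("Macro avg", self.macro_avg),
            ("Weight avg", self.weighted_avg),
        ]
        for name, m in rows:
            lines.append(
                f"{name:12s}{m.precision:>10.2f}{m.recall:>10.2f}{m.f1:>10.2f}{m.support:>10d}"
            )
        lines.append(
            f"Blink matching: TP={self.blink_tp} FP={self.blink_fp} FN={self.blink_fn}"
        )
        return "\n".join(lines)


def _average(
    metrics: Sequence[ClassMetrics], weights: Sequence[float]
) -> ClassMetrics:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum() if w.sum() else np.full(len(metrics), 1 / len(metrics))
    return ClassMetrics(
        precision=float(sum(wi * m.precision for wi, m in zip(w, metrics))),
        recall=float(sum(wi * m.recall for wi, m in zip(w, metrics))),
        f1=float(sum(wi * m.f1 for wi, m in zip(w, metrics))),
        support=int(sum(m.support for m in metrics)),
    )


def evaluate(
    pred: Mapping[int, EyeState],
    gt: GroundTruth,
    events: Sequence[BlinkEvent] = (),
    scores: Mapping[int, float] | None = None,
    prediction_summary: dict | None = None,
    threshold: float | None = None,
) -> EvaluationReport:
    """Assemble the full report from frame labels, scores, events and truth.

    ``scores`` maps frame index to a closedness score (e.g. negated EAR); if
    omitted, or if the truth is single-class, the AUC is reported as None.
    """
    truth_labels = gt.frame_labels
    counts = confusion(pred, truth_labels)
    closed_m = precision_recall_f1(counts)
    open_m = precision_recall_f1(counts.swapped())
    macro = _average([open_m, closed_m], [1, 1])
    weighted = _average([open_m, closed_m], [open_m.support, closed_m.support])

    auc: float | None = None
    if scores is not None:
        common = [
            i for i in set(scores) & set(truth_labels)
            if truth_labels[i] is not EyeState.UNKNOWN and pred.get(i) is not EyeState.UNKNOWN
        ]
        common.sort()
        y = [truth_labels[i] is EyeState.CLOSED for i in common]
        try:
            auc = roc_auc([scores[i] for i in common], y)
        except UndefinedAUCError:
            logger.warning("single-class ground truth; AUC undefined")
            auc = None

    truth_intervals = gt.blink_intervals
    btp, bfp, bfn = match_blinks(events, truth_intervals)

    n_truth_closed = sum(
        1 for s in truth_labels.values() if s is EyeState.CLOSED
    )
    n_truth_known = sum(
        1 for s in truth_labels.values() if s is not EyeState.UNKNOWN
    )
    test_summary = {
        "total_frames_processed": n_truth_known,
        "n_closed_frames": n_truth_closed,
        "n_blinks": len(truth_intervals),
    }
    return EvaluationReport(
        counts=counts,
        per_class={"open": open_m, "closed": closed_m},
        macro_avg=macro,
        weighted_avg=weighted,
        accuracy=counts.accuracy,
        auc=auc,
        blink_tp=btp,
        blink_fp=bfp,
        blink_fn=bfn,
        prediction_summary=prediction_summary,
        test_summary=test_summary,
        threshold=threshold,
    )
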