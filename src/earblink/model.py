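"""Blink-detection model and results objects.

:class:`BlinkDetector` holds the data (an EAR trace, optionally with the
underlying landmark distances) and the run configuration; ``fit()`` estimates
the per-subject Modified EAR threshold (unless a fixed one is requested),
classifies every frame, segments blink events, and returns a
:class:`BlinkDetectionResults` carrying the threshold, states, events,
summary statistics, and — given ground truth — a full evaluation report.

    >>> det = BlinkDetector.from_landmark_file("landmarks.csv")
    >>> res = det.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import GroundTruth
from .errors import ConfigError
from .evaluation import EvaluationReport, evaluate
from .events import BlinkEvent, PredictionSummary, detect_blinks, summarize_predictions
from .geometry import (
    DistanceSummary,
    EarTrace,
    EyeState,
    ModifiedEarThreshold,
    calibrate,
    calibrate_from_trace,
    classify_trace,
    eye_distances,
)
from .io import LandmarkFrameSet, ear_trace_from_landmarks, extract_eyes, read_landmarks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BlinkDetector", "BlinkDetectionResults", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Detection run configuration.

    threshold: "auto" for Modified EAR calibration, or a fixed cut-off such
    as the conventional 0.2 / 0.3.  ``min_consecutive`` is the blink run
    length in frames; ``fc_rule`` ("or"/"and") is how the two FC ground-truth
    flags combine; ``middle`` picks the middle-frame convention.
    """

    threshold: str | float = "auto"
    min_consecutive: int = 3
    fps_override: float | None = None
    fc_rule: str = "or"
    middle: str = "ear_min"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ConfigError(
                    f"threshold must be 'auto' or a number, got {self.threshold!r}"
                )
        elif not np.isfinite(self.threshold) or self.threshold < 0:
            raise ConfigError("fixed threshold must be a finite non-negative number")
        if self.min_consecutive < 1:
            raise ConfigError("min_consecutive must be >= 1")
        if self.fc_rule not in ("or", "and"):
            raise ConfigError("fc_rule must be 'or' or 'and'")
        if self.middle not in ("ear_min", "center"):
            raise ConfigError("middle must be 'ear_min' or 'center'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {"threshold", "min_consecutive", "fps_override", "fc_rule", "middle", "seed"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


class BlinkDetector:
    """Eye-blink detection model over a per-frame EAR trace.

    Parameters
    ----------
    trace
        The per-frame EAR time series (UNKNOWN frames flagged invalid).
    distances
        Optional (n_valid, 3) per-frame averaged (a, b, c) eye distances,
        used for the distance-based Modified EAR calibration; without them
        auto calibration falls back to the EAR-trace min/max midpoint.
    config
        The run configuration.
    """

    def __init__(
        self,
        trace: EarTrace,
        distances: np.ndarray | None = None,
        config: RunConfig | None = None,
    ):
        self.trace = trace
        self.distances = distances
        self.config = config or RunConfig()
        if self.config.fps_override is not None:
            self.trace = EarTrace(trace.samples, fps=self.config.fps_override)

    @classmethod
    def from_landmarks(
        cls, frames: LandmarkFrameSet, config: RunConfig | None = None
    ) -> "BlinkDetector":
        """Build from a landmark frame set, retaining the calibration distances.

        The (a, b, c) distance terms are averaged across the left and right
        eyes per frame before calibration; classification uses the average of
        the two per-eye aspect ratios.
        """
        trace = ear_trace_from_landmarks(frames)
        dists = []
        for eyes in extract_eyes(frames):
            if eyes is None:
                continue
            left, right = eyes
            dl, dr = eye_distances(left), eye_distances(right)
            dists.append([(l + r) / 2.0 for l, r in zip(dl, dr)])
        distances = np.array(dists, dtype=float) if dists else None
        return cls(trace, distances=distances, config=config)

    @classmethod
    def from_landmark_file(
        cls, path: str | Path, config: RunConfig | None = None
    ) -> "BlinkDetector":
        cfg = config or RunConfig()
        frames = read_landmarks(path, fps=cfg.fps_override)
        return cls.from_landmarks(frames, config=cfg)

    def calibrate_threshold(self) -> ModifiedEarThreshold:
        """The threshold the configuration implies (fixed or calibrated)."""
        if self.config.threshold != "auto":
            return ModifiedEarThreshold.fixed(float(self.config.threshold))
        if self.distances is not None and len(self.distances):
            summary = DistanceSummary.from_arrays(
                self.distances[:, 0], self.distances[:, 1], self.distances[:, 2]
            )
            return calibrate(summary)
        return calibrate_from_trace(self.trace)

    def fit(self) -> "BlinkDetectionResults":
        """Calibrate, classify every frame, and segment blink events."""
        thr = self.calibrate_threshold()
        logger.info("using EAR threshold %.4f (%s)", thr.threshold, thr.source)
        states = classify_trace(self.trace, thr)
        events = detect_blinks(
            states,
            fps=self.trace.fps,
            min_consecutive=self.config.min_consecutive,
            trace=self.trace,
            frame_index=[s.frame_index for s in self.trace.samples],
            middle=self.config.middle,
        )
        return BlinkDetectionResults(self, thr, states, events)


@dataclass
class BlinkDetectionResults:
    """Fitted results: threshold estimate, frame states, blink events."""

    model: BlinkDetector
    threshold: ModifiedEarThreshold
    states: list[EyeState]
    events: list[BlinkEvent]

    @property
    def trace(self) -> EarTrace:
        return self.model.trace

    @property
    def frame_labels(self) -> dict[int, EyeState]:
        return {
            s.frame_index: st for s, st in zip(self.trace.samples, self.states)
        }

    @property
    def scores(self) -> dict[int, float]:
        """Closedness score per valid frame: the negated average EAR."""
        return {
            s.frame_index: -s.ear_avg for s in self.trace.samples if s.valid
        }

    @property
    def prediction_summary(self) -> PredictionSummary:
        return summarize_predictions(self.states, self.events)

    def evaluate(self, gt: GroundTruth) -> EvaluationReport:
        """Score the fit against annotated ground truth."""
        ps = self.prediction_summary
        return evaluate(
            self.frame_labels,
            gt,
            events=self.events,
            scores=self.scores,
            prediction_summary={
                "total_frames_processed": ps.total_frames_processed,
                "n_closed_frames": ps.n_closed_frames,
                "n_blinks": ps.n_blinks,
            },
            threshold=self.threshold.threshold,
        )

    def summary(self) -> str:
        """Human-readable fit summary (threshold, counts, first events)."""
        ps = self.prediction_summary
        t = self.threshold
        lines = [
            "Blink detection results",
            "=" * 46,
            f"EAR threshold                 {t.threshold:.4f} ({t.source})",
        ]
        if t.source == "calibrated":
            lines.append(f"  EAR_closed / EAR_open       {t.ear_closed:.4f} / {t.ear_open:.4f}")
        lines += [
            f"fps                           {self.trace.fps:g}",
            f"Total frames processed        {ps.total_frames_processed}",
            f"Number of closed frames       {ps.n_closed_frames}",
            f"Number of blinks              {ps.n_blinks}",
        ]
        for i, ev in enumerate(self.events[:10], start=1):
            lines.append(
                f"  blink {i}: started at frame {ev.start_frame}, "
                f"middle of action at frame {ev.middle_frame}, "
                f"ended at frame {ev.end_frame} ({ev.duration_s * 1000:.0f} ms)"
            )
        if len(self.events) > 10:
            lines.append(f"  ... {len(self.events) - 10} more")
        return "\n".join(lines)

    def events_as_dicts(self) -> list[dict]:
        return [
            {
                "start_frame": e.start_frame,
                "middle_frame": e.middle_frame,
                "end_frame": e.end_frame,
                "duration_frames": e.duration_frames,
                "duration_s": e.duration_s,
            }
            for e in self.events
        ]

    def plot(self, ax=None):
        """Plot the EAR trace, threshold line and detected events."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        idx = self.trace.frame_index
        ax.plot(idx, self.trace.ear_avg, lw=0.8, label="average EAR")
        ax.axhline(self.threshold.threshold, color="r", ls="--", lw=1,
                   label=f"threshold {self.threshold.threshold:.3f}")
        for ev in self.events:
            ax.axvspan(ev.start_frame, ev.end_frame, color="orange", alpha=0.3)
        ax.set_xlabel("frame")
        ax.set_ylabel("EAR")
        ax.legend(loc="upper right", fontsize=8)
        return ax


def run_pipeline(
    frames: LandmarkFrameSet,
    config: RunConfig | None = None,
    ground_truth: GroundTruth | None = None,
) -> tuple[BlinkDetectionResults, EvaluationReport | None]:
    """Landmarks -> EAR -> (calibrate) -> classify -> segment -> (evaluate)."""
    results = BlinkDetector.from_landmarks(frames, config=config).fit()
    report = results.evaluate(ground_truth) if ground_truth is not None else None
    return results, report
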