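"""Blink-event segmentation of the frame-wise eye-state sequence.

A blink is a maximal run of CLOSED frames of length >= ``min_consecutive``
(default 3: at 25-30 fps a physiological 100-400 ms blink spans roughly 3-12
frames).  UNKNOWN frames break a run; runs truncated by the trace boundary
still count if long enough.  Each event is reported by its start, middle and
end frame, the convention used when summarising detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import EarTrace, EyeState

__all__ = ["BlinkEvent", "PredictionSummary", "detect_blinks", "summarize_predictions"]


@dataclass(frozen=True)
class BlinkEvent:
    """One blink: start/middle/end frame indices plus duration."""

    start_frame: int
    middle_frame: int
    end_frame: int
    duration_frames: int
    duration_s: float

    def __post_init__(self) -> None:
        if not self.start_frame <= self.middle_frame <= self.end_frame:
            raise ValueError("blink event frames must satisfy start <= middle <= end")
        if self.duration_frames != self.end_frame - self.start_frame + 1:
            raise ValueError("duration_frames inconsistent with start/end")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start_frame, self.end_frame

    def overlaps(self, start: int, end: int) -> bool:
        return self.start_frame <= end and start <= self.end_frame

    @classmethod
    def from_run(
        cls,
        start: int,
        end: int,
        fps: float,
        trace: EarTrace | None = None,
        middle: str = "ear_min",
    ) -> "BlinkEvent":
        """Build an event from a closed run [start, end] (inclusive, frame indices).

        The middle frame is the frame of minimum average EAR within the run when
        a trace is supplied (``middle="ear_min"``), else the central frame; ties
        resolve to the earliest frame.
        """
        n = end - start + 1
        if trace is not None and middle == "ear_min":
            idx = trace.frame_index
            ear = trace.ear_avg
            mask = (idx >= start) & (idx <= end)
            if mask.any() and np.isfinite(ear[mask]).any():
                sub_idx = idx[mask]
                sub_ear = ear[mask]
                # nanargmin with earliest-tie preference: argmin on masked array
                pos = int(np.nanargmin(sub_ear))
                mid = int(sub_idx[pos])
            else:
                mid = start + (n - 1) // 2
        else:
            mid = start + (n - 1) // 2
        return cls(start, mid, end, n, n / fps)


def detect_blinks(
    states: Sequence[EyeState],
    fps: float,
    min_consecutive: int = 3,
    trace: EarTrace | None = None,
    frame_index: Sequence[int] | None = None,
    middle: str = "ear_min",
) -> list[BlinkEvent]:
    """Segment the eye-state sequence into blink events.

    Parameters
    ----------
    states
        Frame-wise OPEN/CLOSED/UNKNOWN labels, one per frame, in frame order.
    fps
        Frame rate, for event durations in seconds.
    min_consecutive
        Minimum run length (frames) of CLOSED for a run to count as a blink.
    trace
        Optional EAR trace aligned with ``states``; enables the EAR-minimum
        middle-frame convention.
    frame_index
        Frame indices of ``states``; defaults to 0..n-1.
    middle
        "ear_min" (default, needs ``trace``) or "center".

    Returns
    -------
    list of BlinkEvent, in order, non-overlapping.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    if len(states) == 0:
        raise ValueError("states must be non-empty")
    if frame_index is None:
        frame_index = list(range(len(states)))
    if len(frame_index) != len(states):
        raise ValueError("frame_index and states lengths differ")

    events: list[BlinkEvent] = []
    run_start: int | None = None
    prev_idx: int | None = None

    def flush(end_idx: int) -> None:
        nonlocal run_start
        if run_start is not None:
            if end_idx - run_start + 1 >= min_consecutive:
                events.append(
                    BlinkEvent.from_run(run_start, end_idx, fps, trace=trace, middle=middle)
                )
            run_start = None

    for idx, state in zip(frame_index, states):
        # a gap in the frame index also breaks a run
        contiguous = prev_idx is None or idx == prev_idx + 1
        if state is EyeState.CLOSED and contiguous and run_start is not None:
            pass  # run continues
        else:
            if prev_idx is not None:
                flush(prev_idx)
            run_start = idx if state is EyeState.CLOSED else None
        prev_idx = idx
    if prev_idx is not None:
        flush(prev_idx)
    return events


@dataclass(frozen=True)
class PredictionSummary:
    """Prediction-set statistics: frames processed, closed frames, blink count."""

    total_frames_processed: int
    n_closed_frames: int
    n_blinks: int

    def __post_init__(self) -> None:
        if self.n_closed_frames > self.total_frames_processed:
            raise ValueError("closed frames cannot exceed processed frames")


def summarize_predictions(
    states: Sequence[EyeState], events: Sequence[BlinkEvent]
) -> PredictionSummary:
    """Count processed (non-UNKNOWN) frames, CLOSED frames and blink events."""
    processed = sum(1 for s in states if s is not EyeState.UNKNOWN)
    closed = sum(1 for s in states if s is EyeState.CLOSED)
    return PredictionSummary(processed, closed, len(events))
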