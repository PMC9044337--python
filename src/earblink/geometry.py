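"""Eye-aspect-ratio geometry, per-subject threshold calibration, and frame classification.

The eye aspect ratio (EAR) condenses the six eye-contour landmarks P1..P6
(P1 outer corner, P4 inner corner, P2/P3 upper lid, P6/P5 lower lid) into a
single scalar of eye openness:

    EAR = (||P2 - P6|| + ||P3 - P5||) / (2 ||P1 - P4||)

It is invariant under translation, rotation and uniform scaling of the face,
stays roughly constant while the eye is open and collapses toward zero during
a blink.  Because baseline openness varies between subjects, a fixed cut-off
(0.2 or 0.3 are common choices) misclassifies small or large eyes; the
Modified EAR threshold instead calibrates a per-subject decision boundary from
the observed extremes of the three landmark distances:

    EAR_closed = (min||P2-P6|| + min||P3-P5||) / (2 max||P1-P4||)
    EAR_open   = (max||P2-P6|| + max||P3-P5||) / (2 min||P1-P4||)
    threshold  = (EAR_open + EAR_closed) / 2

A frame is labelled CLOSED when its EAR is at or below the threshold, OPEN
otherwise; frames without landmarks are UNKNOWN.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, DegenerateEyeError

__all__ = [
    "EyePoints",
    "EyeState",
    "EarSample",
    "EarTrace",
    "DistanceSummary",
    "ModifiedEarThreshold",
    "compute_ear",
    "average_ear",
    "eye_distances",
    "summarize_distances",
    "calibrate",
    "classify_frame",
    "classify_trace",
]

Point = tuple[float, float]


class EyeState(enum.Enum):
    """Per-frame eye status; UNKNOWN is reserved for frames without landmarks."""

    OPEN = "open"
    CLOSED = "closed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class EyePoints:
    """The six 2-D eye-contour landmarks of one eye in one frame (pixels).

    P1 is the outer corner, P4 the inner corner, P2/P3 the upper lid and
    P6/P5 the lower lid, so that a = ||P2-P6|| and b = ||P3-P5|| are the two
    vertical lid distances and c = ||P1-P4|| the horizontal width.
    """

    p1: Point
    p2: Point
    p3: Point
    p4: Point
    p5: Point
    p6: Point

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5", "p6"):
            x, y = getattr(self, name)
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"{name} has non-finite coordinates: ({x}, {y})")

    def as_array(self) -> np.ndarray:
        """(6, 2) array in P1..P6 order."""
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5, self.p6], dtype=float)


def _dist(u: Point, v: Point) -> float:
    return math.hypot(u[0] - v[0], u[1] - v[1])


def eye_distances(eye: EyePoints) -> tuple[float, float, float]:
    """The (a, b, c) distance triple: upper/lower lid gaps and corner width."""
    return _dist(eye.p2, eye.p6), _dist(eye.p3, eye.p5), _dist(eye.p1, eye.p4)


def compute_ear(eye: EyePoints) -> float:
    """Eye aspect ratio (a + b) / (2c) of one eye.

    Raises
    ------
    DegenerateEyeError
        If the corner width c = ||P1-P4|| is zero.
    """
    a, b, c = eye_distances(eye)
    if c == 0.0:
        raise DegenerateEyeError("eye corners coincide (||P1-P4|| = 0); EAR undefined")
    return (a + b) / (2.0 * c)


def average_ear(left: float, right: float) -> float:
    """Arithmetic mean of the left- and right-eye aspect ratios."""
    return 0.5 * (left + right)


@dataclass(frozen=True)
class EarSample:
    """One frame of an EAR time series."""

    frame_index: int
    ear_left: float
    ear_right: float
    ear_avg: float
    valid: bool = True

    @classmethod
    def from_eyes(cls, frame_index: int, left: EyePoints, right: EyePoints) -> "EarSample":
        el, er = compute_ear(left), compute_ear(right)
        return cls(frame_index, el, er, average_ear(el, er), True)

    @classmethod
    def invalid(cls, frame_index: int) -> "EarSample":
        return cls(frame_index, math.nan, math.nan, math.nan, False)


@dataclass
class EarTrace:
    """Ordered per-frame EAR samples with the video frame rate."""

    samples: list[EarSample]
    fps: float

    def __post_init__(self) -> None:
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ValueError(f"fps must be finite and positive, got {self.fps}")
        idx = [s.frame_index for s in self.samples]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def frame_index(self) -> np.ndarray:
        return np.array([s.frame_index for s in self.samples], dtype=int)

    @property
    def ear_avg(self) -> np.ndarray:
        return np.array([s.ear_avg for s in self.samples], dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return np.array([s.valid for s in self.samples], dtype=bool)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fps


@dataclass(frozen=True)
class DistanceSummary:
    """Per-term extremes of the (a, b, c) eye distances over the valid frames.

    Minima and maxima are taken independently per term, so they may come from
    different frames.
    """

    a_min: float
    a_max: float
    b_min: float
    b_max: float
    c_min: float
    c_max: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise CalibrationError("distance summary needs at least one valid frame")
        for lo, hi, name in (
            (self.a_min, self.a_max, "a"),
            (self.b_min, self.b_max, "b"),
            (self.c_min, self.c_max, "c"),
        ):
            if lo > hi:
                raise CalibrationError(f"{name}_min > {name}_max in distance summary")
        if self.c_min <= 0:
            raise CalibrationError("eye width c must be positive in every frame")

    @classmethod
    def from_arrays(
        cls, a: np.ndarray, b: np.ndarray, c: np.ndarray
    ) -> "DistanceSummary":
        a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
        if a.size == 0:
            raise CalibrationError("cannot summarize an empty distance trace")
        return cls(
            a_min=float(a.min()), a_max=float(a.max()),
            b_min=float(b.min()), b_max=float(b.max()),
            c_min=float(c.min()), c_max=float(c.max()),
            n_frames=int(a.size),
        )


def summarize_distances(frames: Sequence[EyePoints] | Iterable[EyePoints]) -> DistanceSummary:
    """Scan a sequence of eye landmark frames into per-term distance extremes."""
    triples = [eye_distances(eye) for eye in frames]
    if not triples:
        raise CalibrationError("cannot calibrate from an empty frame sequence")
    arr = np.array(triples, dtype=float)
    return DistanceSummary.from_arrays(arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass(frozen=True)
class ModifiedEarThreshold:
    """Calibrated (or fixed) EAR decision threshold with its provenance.

    For a calibrated threshold, ``ear_closed`` and ``ear_open`` bracket every
    per-frame EAR of the calibration trace and ``threshold`` is their midpoint.
    A fixed threshold (e.g. the conventional 0.2 or 0.3) carries
    ``ear_closed == ear_open == threshold`` and ``source == "fixed"``.
    """

    ear_closed: float
    ear_open: float
    threshold: float
    source: str = "calibrated"  # "fixed" | "calibrated"

    def __post_init__(self) -> None:
        if self.source not in ("fixed", "calibrated"):
            raise ValueError(f"unknown threshold source {self.source!r}")
        if not self.ear_closed <= self.threshold <= self.ear_open:
            raise ValueError("threshold must lie between ear_closed and ear_open")

    @classmethod
    def fixed(cls, value: float) -> "ModifiedEarThreshold":
        return cls(ear_closed=value, ear_open=value, threshold=value, source="fixed")


def calibrate(summary: DistanceSummary) -> ModifiedEarThreshold:
    """Per-subject Modified EAR threshold from the distance extremes.

    ear_closed = (a_min + b_min) / (2 c_max), ear_open = (a_max + b_max) / (2 c_min),
    threshold = their midpoint.
    """
    if summary.c_min <= 0 or summary.c_max <= 0:
        raise CalibrationError("degenerate eye width; cannot calibrate")
    ear_closed = (summary.a_min + summary.b_min) / (2.0 * summary.c_max)
    ear_open = (summary.a_max + summary.b_max) / (2.0 * summary.c_min)
    return ModifiedEarThreshold(
        ear_closed=ear_closed,
        ear_open=ear_open,
        threshold=(ear_open + ear_closed) / 2.0,
        source="calibrated",
    )


def calibrate_from_trace(trace: EarTrace) -> ModifiedEarThreshold:
    """Calibrate from an EAR trace alone (no landmark distances retained).

    Uses the min/max of the valid average-EAR samples as EAR_closed/EAR_open.
    With a constant eye-corner width this equals the distance-based calibration
    exactly; with a varying width it is a close surrogate.
    """
    ear = np.array([s.ear_avg for s in trace.samples if s.valid], dtype=float)
    if ear.size == 0:
        raise CalibrationError("no valid frames to calibrate from")
    lo, hi = float(ear.min()), float(ear.max())
    return ModifiedEarThreshold(
        ear_closed=lo, ear_open=hi, threshold=(hi + lo) / 2.0, source="calibrated"
    )


def classify_frame(ear: float, thr: ModifiedEarThreshold | float) -> EyeState:
    """CLOSED if EAR <= threshold, OPEN otherwise.

    Equality maps to CLOSED: the decision rule assigns both classes at the
    boundary, and "EAR smaller than the threshold means closed" is the reading
    used throughout this package.
    """
    t = thr.threshold if isinstance(thr, ModifiedEarThreshold) else float(thr)
    if math.isnan(ear):
        return EyeState.UNKNOWN
    return EyeState.CLOSED if ear <= t else EyeState.OPEN


def classify_trace(
    trace: EarTrace, thr: ModifiedEarThreshold | float
) -> list[EyeState]:
    """Frame-wise classification of a whole trace; invalid frames → UNKNOWN."""
    out = []
    for s in trace.samples:
        if not s.valid:
            out.append(EyeState.UNKNOWN)
        else:
            out.append(classify_frame(s.ear_avg, thr))
    return out
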