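"""Landmark-trace file I/O and eye-region extraction.

The on-disk layout is a wide CSV, one row per frame, columns
``frame_id,x0,y0,...,x67,y67`` following the 68-point facial-landmark
convention (jaw 0-16, brows 17-26, nose 27-35, right eye 36-41, left eye
42-47, mouth 48-67; 0-based).  Optional ``# key=value`` comment lines before
the header carry metadata, in particular ``# fps=30``.  Some annotation
dialects quote the same eye points 1-based (37-42 / 43-48); this module is
strictly 0-based and that shift is a documented I/O concern only.

Frames absent from the file (gaps in frame_id) or containing non-finite
coordinates are marked invalid and propagate as UNKNOWN downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationParseError, DataError
from .geometry import EarSample, EarTrace, EyePoints

__all__ = [
    "LandmarkFrameSet",
    "VideoInfo",
    "read_landmarks",
    "extract_eyes",
    "ear_trace_from_landmarks",
    "RIGHT_EYE_SLICE",
    "LEFT_EYE_SLICE",
]

RIGHT_EYE_SLICE = slice(36, 42)
LEFT_EYE_SLICE = slice(42, 48)


@dataclass(frozen=True)
class VideoInfo:
    """Frame count and frame rate of a recording."""

    frame_count: int
    fps: float

    @property
    def duration_s(self) -> float:
        return self.frame_count / self.fps


@dataclass
class LandmarkFrameSet:
    """Per-frame 68-point landmarks with validity flags and source metadata."""

    frame_ids: np.ndarray  # (n,) int, strictly increasing, contiguous
    points: np.ndarray  # (n, 68, 2) float; NaN where invalid
    valid: np.ndarray  # (n,) bool
    fps: float
    origin: str = ""

    def __post_init__(self) -> None:
        if self.points.shape[1:] != (68, 2):
            raise DataError(f"expected (n, 68, 2) points, got {self.points.shape}")
        if len(self.frame_ids) != len(self.points) or len(self.valid) != len(self.points):
            raise DataError("frame_ids/points/valid lengths differ")
        if np.any(np.diff(self.frame_ids) <= 0):
            raise DataError("frame ids must be unique and increasing")

    def __len__(self) -> int:
        return len(self.frame_ids)

    @property
    def video_info(self) -> VideoInfo:
        return VideoInfo(frame_count=len(self), fps=self.fps)


def read_landmarks(path: str | Path, fps: float | None = None) -> LandmarkFrameSet:
    """Read the wide landmark CSV into a validated :class:`LandmarkFrameSet`.

    ``fps`` overrides the ``# fps=`` metadata line; if neither is present a
    default of 30 is assumed (the typical webcam rate).  Gaps in frame_id
    become invalid frames so the frame set is contiguous.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise AnnotationParseError(f"empty landmark file: {path}")
    expected_cols = ["frame_id"] + [f"{ax}{i}" for i in range(68) for ax in ("x", "y")]
    if list(df.columns) != expected_cols:
        raise AnnotationParseError(
            f"landmark CSV must have columns frame_id,x0,y0,...,x67,y67 "
            f"(got {len(df.columns)} columns)"
        )
    if len(df) == 0:
        raise AnnotationParseError(f"landmark file has no frames: {path}")
    if df["frame_id"].duplicated().any():
        dup = int(df["frame_id"][df["frame_id"].duplicated()].iloc[0])
        raise AnnotationParseError(f"duplicate frame_id {dup} in landmark file")

    if fps is None:
        fps = float(meta.get("fps", 30.0))
    if fps <= 0:
        raise DataError("fps must be positive")

    present_ids = df["frame_id"].to_numpy(dtype=int)
    lo, hi = int(present_ids.min()), int(present_ids.max())
    n = hi - lo + 1
    frame_ids = np.arange(lo, hi + 1)
    points = np.full((n, 68, 2), np.nan)
    coords = df[expected_cols[1:]].to_numpy(dtype=float).reshape(len(df), 68, 2)
    points[present_ids - lo] = coords
    valid = np.isfinite(points).all(axis=(1, 2))
    return LandmarkFrameSet(frame_ids, points, valid, fps=fps, origin=str(path))


def extract_eyes(frames: LandmarkFrameSet) -> list[tuple[EyePoints, EyePoints] | None]:
    """Per-frame (left, right) eye landmark sextets; None for invalid frames.

    The right eye occupies 0-based points 36-41 and the left eye 42-47, each
    already ordered P1..P6 (corner, upper lid x2, corner, lower lid x2).
    """
    out: list[tuple[EyePoints, EyePoints] | None] = []
    for i in range(len(frames)):
        if not frames.valid[i]:
            out.append(None)
            continue
        right = EyePoints(*map(tuple, frames.points[i, RIGHT_EYE_SLICE]))
        left = EyePoints(*map(tuple, frames.points[i, LEFT_EYE_SLICE]))
        out.append((left, right))
    return out


def ear_trace_from_landmarks(frames: LandmarkFrameSet) -> EarTrace:
    """Compute the per-frame (left, right, average) EAR trace."""
    samples: list[EarSample] = []
    for fid, eyes in zip(frames.frame_ids, extract_eyes(frames)):
        if eyes is None:
            samples.append(EarSample.invalid(int(fid)))
        else:
            left, right = eyes
            samples.append(EarSample.from_eyes(int(fid), left, right))
    return EarTrace(samples, fps=frames.fps)
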