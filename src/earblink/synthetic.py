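"""Ground-truthed synthetic eyelid traces, landmark files and annotation files.

The generator emulates what a facial-landmark tracker produces on a video of
a blinking subject: a per-frame eye-aspect-ratio trace that sits at an open
baseline and dips rapidly toward a closed value during each blink, plus
additive Gaussian tracker noise.  Blink rate and duration default to the
physiological ranges (6-30 blinks/min, 100-400 ms per blink).

Each blink is a trapezoidal close-hold-open dip.  The dip is sized so that
the run of frames at or below the half-amplitude midpoint
(ear_open_mean + ear_closed_mean)/2 spans exactly the configured blink
duration; ramp samples are placed at fractions (i - 1/2)/R of the descent so
that no sampled value ever lands exactly on the midpoint.  Ground-truth blink
events use this half-amplitude convention (the standard onset/offset
criterion in blink kinematics), which makes noise-free threshold re-detection
exact: the calibrated Modified EAR threshold of a noise-free trace *is* that
midpoint.

``export_fixture`` materialises a trace as the wide 68-point landmark CSV
(both eyes built by :func:`synthesize_eye`, the remaining points from a fixed
face template) and a matching Eyeblink8-dialect annotation file whose FC
flags mark exactly the ground-truth closed frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationRecord, GroundTruth, write_annotations
from .errors import ConfigError
from .events import BlinkEvent
from .geometry import EarSample, EarTrace, EyePoints

__all__ = [
    "BlinkSimConfig",
    "SimulatedTrace",
    "simulate_ear_trace",
    "synthesize_eye",
    "export_fixture",
]


@dataclass(frozen=True)
class BlinkSimConfig:
    """Simulation parameters.

    Defaults describe a plausible webcam recording of a resting subject:
    30 fps, one minute, 12 blinks/min of 200 ms each, an open-eye EAR of 0.32
    and a closed-eye EAR of 0.08 (bracketing the conventional 0.2/0.3
    cut-offs), and light tracker noise.
    """

    fps: float = 30.0
    duration_s: float = 60.0
    blink_rate_per_min: float = 12.0
    blink_duration_ms: float = 200.0
    ear_open_mean: float = 0.32
    ear_closed_mean: float = 0.08
    noise_sd: float = 0.01
    eye_width_px: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if not self.ear_closed_mean < self.ear_open_mean:
            raise ConfigError("ear_closed_mean must be below ear_open_mean")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.eye_width_px <= 0:
            raise ConfigError("eye_width_px must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def n_blinks(self) -> int:
        return int(round(self.blink_rate_per_min * self.duration_s / 60.0))

    @property
    def blink_duration_frames(self) -> int:
        return max(1, int(round(self.blink_duration_ms * self.fps / 1000.0)))

    @property
    def midpoint(self) -> float:
        return (self.ear_open_mean + self.ear_closed_mean) / 2.0


@dataclass(frozen=True)
class SimulatedTrace:
    """A simulated EAR trace with its ground truth and the config that made it."""

    ear_trace: EarTrace
    truth_events: list[BlinkEvent]
    clean_ear: np.ndarray
    config: BlinkSimConfig


def _dip_profile(cfg: BlinkSimConfig) -> tuple[np.ndarray, int]:
    """One blink dip as per-frame EAR values.

    Returns (values, n_below): the dip samples and how many of its leading
    frames lie above the midpoint (the closing ramp's upper half), so callers
    can align the half-amplitude run.  Layout: R descending ramp samples at
    fractions (i-1/2)/R, a plateau at ear_closed_mean, then the mirrored
    ascending ramp.  The plateau length is chosen so the run of values at or
    below the midpoint spans exactly ``blink_duration_frames``.
    """
    dur = cfg.blink_duration_frames
    ramp = max(1, int(round(dur / 3.0)))
    below_per_ramp = ramp // 2  # ramp samples strictly below the midpoint
    plateau = max(1, dur - 2 * below_per_ramp)
    open_, closed = cfg.ear_open_mean, cfg.ear_closed_mean
    fracs = (np.arange(1, ramp + 1) - 0.5) / ramp  # never exactly 1/2
    down = open_ + (closed - open_) * fracs
    values = np.concatenate([down, np.full(plateau, closed), down[::-1]])
    n_above_lead = int(np.sum(values[:ramp] > cfg.midpoint))
    return values, n_above_lead


def _place_onsets(
    rng: np.random.Generator, n_blinks: int, n_frames: int, dip_len: int
) -> np.ndarray:
    """Uniform non-overlapping blink onsets by rejection sampling.

    A one-frame open gap is enforced between consecutive dips so that distinct
    blinks can never merge into one closed run.
    """
    if n_blinks == 0:
        return np.array([], dtype=int)
    slot = dip_len + 1
    if n_blinks * slot > n_frames:
        raise ConfigError(
            f"cannot place {n_blinks} blinks of {dip_len} frames in {n_frames} frames"
        )
    for _ in range(10_000):
        onsets = np.sort(rng.integers(0, n_frames - dip_len + 1, size=n_blinks))
        if n_blinks == 1 or np.all(np.diff(onsets) >= slot):
            return onsets
    # dense regimes: fall back to a jittered regular grid, still seeded
    spacing = n_frames // n_blinks
    if spacing < slot:
        raise ConfigError("blink rate times duration exceeds trace capacity")
    jitter = rng.integers(0, spacing - dip_len + 1, size=n_blinks)
    return np.arange(n_blinks) * spacing + jitter


def simulate_ear_trace(cfg: BlinkSimConfig) -> SimulatedTrace:
    """Simulate a seeded EAR trace with ground-truth blink events.

    The baseline sits at ``ear_open_mean``; ``n_blinks`` trapezoidal dips are
    placed uniformly without overlap; Gaussian noise of sd ``noise_sd`` is
    added to every frame.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    clean = np.full(n, cfg.ear_open_mean, dtype=float)
    dip, lead_above = _dip_profile(cfg)
    onsets = _place_onsets(rng, cfg.n_blinks, n, len(dip))

    truth: list[BlinkEvent] = []
    for onset in onsets:
        clean[onset : onset + len(dip)] = dip
        start = int(onset) + lead_above
        end = int(onset) + len(dip) - 1 - lead_above
        truth.append(BlinkEvent(start, start + (end - start) // 2, end, end - start + 1,
                                (end - start + 1) / cfg.fps))

    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else clean.copy()
    noisy = np.maximum(noisy, 0.0)  # an aspect ratio cannot be negative

    samples = [
        EarSample(i, float(v), float(v), float(v), True) for i, v in enumerate(noisy)
    ]
    return SimulatedTrace(
        ear_trace=EarTrace(samples, fps=cfg.fps),
        truth_events=truth,
        clean_ear=clean,
        config=cfg,
    )


def synthesize_eye(ear: float, width: float = 50.0) -> EyePoints:
    """Six eye landmarks realising a given aspect ratio exactly.

    P1=(0,0), P4=(w,0) fix the corner width; the four lid points sit at
    x = w/4 and 3w/4, y = ±h/2 with h = ear·w, so that
    (h + h) / (2w) = ear by construction.
    """
    if ear < 0:
        raise ValueError("ear must be >= 0")
    if width <= 0:
        raise ValueError("width must be positive")
    w, h = float(width), float(ear) * float(width)
    return EyePoints(
        p1=(0.0, 0.0),
        p2=(w / 4.0, h / 2.0),
        p3=(3.0 * w / 4.0, h / 2.0),
        p4=(w, 0.0),
        p5=(3.0 * w / 4.0, -h / 2.0),
        p6=(w / 4.0, -h / 2.0),
    )


# Fixed face template: where each of the 68 landmark points sits in a
# 640x480 frame for the synthetic subject.  Only the eye points (36-47) vary
# with the simulated EAR; the rest are static scaffolding so files have the
# full 68-point layout.
FACE_BOX = (220.0, 160.0, 200.0, 200.0)  # x, y, w, h
RIGHT_EYE_ORIGIN = (250.0, 225.0)  # outer corner of right eye (0-based pts 36-41)
LEFT_EYE_ORIGIN = (330.0, 225.0)  # outer-corner anchor of left eye (pts 42-47)


def _template_points() -> np.ndarray:
    """Static 68x2 template; eye slots are overwritten per frame."""
    pts = np.zeros((68, 2))
    # jaw 0-16: arc across the face box
    for i in range(17):
        pts[i] = (FACE_BOX[0] + FACE_BOX[2] * i / 16.0, FACE_BOX[1] + 180.0)
    # brows 17-26
    for i in range(17, 27):
        pts[i] = (FACE_BOX[0] + 20.0 + 16.0 * (i - 17), FACE_BOX[1] + 40.0)
    # nose 27-35
    for i in range(27, 36):
        pts[i] = (320.0, 200.0 + 8.0 * (i - 27))
    # mouth/lips 48-67
    for i in range(48, 68):
        pts[i] = (260.0 + 6.0 * (i - 48), 320.0)
    return pts


def frame_landmarks(ear: float, width: float) -> np.ndarray:
    """68x2 landmark array for one frame at the given per-eye aspect ratio."""
    pts = _template_points()
    eye = synthesize_eye(ear, width).as_array()
    pts[36:42] = eye + np.array(RIGHT_EYE_ORIGIN)
    pts[42:48] = eye + np.array(LEFT_EYE_ORIGIN)
    return pts


def export_fixture(
    trace: SimulatedTrace, out_dir: str | Path, stem: str = "synthetic"
) -> tuple[Path, Path]:
    """Write the landmark CSV and annotation file for a simulated trace.

    The landmark CSV has columns ``frame_id,x0,y0,...,x67,y67`` plus a
    ``# fps=...`` comment header.  The annotation file marks both eyes' FC
    flags ``C`` on every ground-truth closed frame and numbers blinks 1..k.
    Returns (landmark_path, annotation_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lm_path = out_dir / f"{stem}_landmarks.csv"
    ann_path = out_dir / f"{stem}_annotations.txt"

    cfg = trace.config
    w = cfg.eye_width_px

    header = ["frame_id"] + [f"{ax}{i}" for i in range(68) for ax in ("x", "y")]
    lines = [f"# fps={cfg.fps:g}", ",".join(header)]
    for s in trace.ear_trace.samples:
        pts = frame_landmarks(s.ear_avg, w)
        row = [str(s.frame_index)] + [f"{v:.6f}" for v in pts.ravel()]
        lines.append(",".join(row))
    lm_path.write_text("\n".join(lines) + "\n")

    # frame -> blink id for ground-truth closed frames
    blink_of: dict[int, int] = {}
    for k, ev in enumerate(trace.truth_events, start=1):
        for f in range(ev.start_frame, ev.end_frame + 1):
            blink_of[f] = k

    records = []
    fx, fy, fw, fh = FACE_BOX
    for s in trace.ear_trace.samples:
        f = s.frame_index
        closed = f in blink_of
        rec = AnnotationRecord(
            frame_id=f,
            blink_id=blink_of.get(f),
            nf="X",
            le_fc="C" if closed else "X",
            le_nv="X",
            re_fc="C" if closed else "X",
            re_nv="X",
            f_x=fx, f_y=fy, f_w=fw, f_h=fh,
            le_lx=LEFT_EYE_ORIGIN[0], le_ly=LEFT_EYE_ORIGIN[1],
            le_rx=LEFT_EYE_ORIGIN[0] + w, le_ry=LEFT_EYE_ORIGIN[1],
            re_lx=RIGHT_EYE_ORIGIN[0], re_ly=RIGHT_EYE_ORIGIN[1],
            re_rx=RIGHT_EYE_ORIGIN[0] + w, re_ry=RIGHT_EYE_ORIGIN[1],
        )
        records.append(rec)
    write_annotations(GroundTruth(records), ann_path)
    return lm_path, ann_path
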