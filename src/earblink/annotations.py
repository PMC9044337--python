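"""Reader/writer for the Eyeblink8-style colon-separated blink annotation dialect.

An annotation file begins with a ``#start`` line; every following row carries
19 colon-separated fields::

    frame ID : blink ID : NF : LE_FC : LE_NV : RE_FC : RE_NV :
    F_X : F_Y : F_W : F_H : LE_LX : LE_LY : LE_RX : LE_RY :
    RE_LX : RE_LY : RE_RX : RE_RY

``blink ID`` groups consecutive frames of one blink (``X`` or empty when the
frame belongs to no blink).  ``FC`` flags (``C``) mark a frame whose eye is
fully closed (90-100% closure); ``NV`` flags (``N``) mark an eye that is not
visible (occlusion, lighting, head motion); ``NF`` marks a non-frontal face.
The remaining fields are the face bounding box and the four eye-corner
positions in pixels.

Frame-level ground truth derives from the flags: a frame is *closed* when
either eye's FC flag is ``C`` (configurable to require both), *unknown* when
both NV flags are ``N``, and *open* otherwise.  Blink intervals are the
maximal runs of records sharing a blink ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import AnnotationParseError
from .geometry import EyeState

__all__ = [
    "AnnotationRecord",
    "BlinkInterval",
    "GroundTruth",
    "parse_annotation_line",
    "read_annotations",
    "write_annotations",
    "HEADER",
]

HEADER = "#start"

_FLAG_ALPHABETS = {
    "nf": {"X", "N"},
    "le_fc": {"X", "C"},
    "le_nv": {"X", "N"},
    "re_fc": {"X", "C"},
    "re_nv": {"X", "N"},
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated frame in the 19-field dialect."""

    frame_id: int
    blink_id: int | None
    nf: str
    le_fc: str
    le_nv: str
    re_fc: str
    re_nv: str
    f_x: float
    f_y: float
    f_w: float
    f_h: float
    le_lx: float
    le_ly: float
    le_rx: float
    le_ry: float
    re_lx: float
    re_ly: float
    re_rx: float
    re_ry: float

    def __post_init__(self) -> None:
        if self.frame_id < 0:
            raise ValueError("frame_id must be >= 0")
        if self.f_w < 0 or self.f_h < 0:
            raise ValueError("face box width/height must be >= 0")
        for name, alphabet in _FLAG_ALPHABETS.items():
            if getattr(self, name) not in alphabet:
                raise ValueError(
                    f"flag {name}={getattr(self, name)!r} not in {sorted(alphabet)}"
                )

    def frame_label(self, fc_rule: str = "or") -> EyeState:
        """Closed/open/unknown label for this frame under the FC rule."""
        if self.le_nv == "N" and self.re_nv == "N":
            return EyeState.UNKNOWN
        closed_flags = (self.le_fc == "C", self.re_fc == "C")
        closed = any(closed_flags) if fc_rule == "or" else all(closed_flags)
        return EyeState.CLOSED if closed else EyeState.OPEN

    def to_line(self) -> str:
        blink = "X" if self.blink_id is None else str(self.blink_id)
        fmt = lambda v: format(v, "g")
        fields = [
            str(self.frame_id), blink,
            self.nf, self.le_fc, self.le_nv, self.re_fc, self.re_nv,
            fmt(self.f_x), fmt(self.f_y), fmt(self.f_w), fmt(self.f_h),
            fmt(self.le_lx), fmt(self.le_ly), fmt(self.le_rx), fmt(self.le_ry),
            fmt(self.re_lx), fmt(self.re_ly), fmt(self.re_rx), fmt(self.re_ry),
        ]
        return ": ".join(fields)


@dataclass(frozen=True)
class BlinkInterval:
    """A ground-truth blink: consecutive frames sharing a blink ID."""

    blink_id: int
    start_frame: int
    end_frame: int

    def overlaps(self, start: int, end: int) -> bool:
        return self.start_frame <= end and start <= self.end_frame


@dataclass
class GroundTruth:
    """Parsed annotation file: records, per-frame labels and blink intervals."""

    records: list[AnnotationRecord]
    fc_rule: str = "or"

    def __post_init__(self) -> None:
        if self.fc_rule not in ("or", "and"):
            raise ValueError("fc_rule must be 'or' or 'and'")
        seen: set[int] = set()
        for rec in self.records:
            if rec.frame_id in seen:
                raise AnnotationParseError(f"duplicate frame_id {rec.frame_id}")
            seen.add(rec.frame_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.records == other.records

    @property
    def frame_labels(self) -> dict[int, EyeState]:
        return {r.frame_id: r.frame_label(self.fc_rule) for r in self.records}

    @property
    def blink_intervals(self) -> list[BlinkInterval]:
        """Maximal runs of records sharing a (non-absent) blink ID, in file order."""
        intervals: list[BlinkInterval] = []
        cur_id: int | None = None
        cur_start = cur_end = -1
        for rec in self.records:
            if rec.blink_id is not None and rec.blink_id == cur_id:
                cur_end = rec.frame_id
            else:
                if cur_id is not None:
                    intervals.append(BlinkInterval(cur_id, cur_start, cur_end))
                cur_id = rec.blink_id
                cur_start = cur_end = rec.frame_id
        if cur_id is not None:
            intervals.append(BlinkInterval(cur_id, cur_start, cur_end))
        return intervals

    def to_frame_csv(self, path: str | Path) -> None:
        """Two-column frame_id,label CSV export (open/closed/unknown)."""
        lines = ["frame_id,label"]
        for frame_id, label in self.frame_labels.items():
            lines.append(f"{frame_id},{label.value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_blink_id(token: str) -> int | None:
    token = token.strip()
    if token in ("", "X"):
        return None
    try:
        return int(token)
    except ValueError:
        return None


def parse_annotation_line(line: str, line_number: int | None = None) -> AnnotationRecord | None:
    """Parse one annotation line; header/comment lines return None.

    Whitespace around the colon separators is tolerated.  A wrong field count
    or a non-numeric coordinate raises :class:`AnnotationParseError` carrying
    the line number.
    """
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    fields = [f.strip() for f in stripped.split(":")]
    if len(fields) != 19:
        raise AnnotationParseError(
            f"expected 19 colon-separated fields, got {len(fields)}", line_number
        )
    try:
        frame_id = int(fields[0])
    except ValueError:
        raise AnnotationParseError(f"non-numeric frame ID {fields[0]!r}", line_number)
    blink_id = _parse_blink_id(fields[1])
    flags = fields[2:7]
    try:
        coords = [float(f) for f in fields[7:]]
    except ValueError as exc:
        raise AnnotationParseError(f"non-numeric coordinate: {exc}", line_number)
    try:
        return AnnotationRecord(frame_id, blink_id, *flags, *coords)
    except ValueError as exc:
        raise AnnotationParseError(str(exc), line_number)


def read_annotations(path: str | Path, fc_rule: str = "or") -> GroundTruth:
    """Read an annotation file into a :class:`GroundTruth`."""
    records: list[AnnotationRecord] = []
    with open(path, "r") as fh:
        for i, line in enumerate(fh, start=1):
            rec = parse_annotation_line(line, line_number=i)
            if rec is not None:
                records.append(rec)
    return GroundTruth(records, fc_rule=fc_rule)


def write_annotations(gt: GroundTruth, path: str | Path) -> None:
    """Write a GroundTruth back to the colon-separated dialect (round-trip safe)."""
    lines = [HEADER] + [rec.to_line() for rec in gt.records]
    Path(path).write_text("\n".join(lines) + "\n")
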