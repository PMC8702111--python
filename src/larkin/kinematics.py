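"""Laryngeal-elevation measurement from per-frame structure masks.

The chain: per-frame midpoints of the TVC (thyroid cartilage + vocal fold
complex) and of the C1 spinous process -> the TVC midpoint *relative* to the
C1 midpoint (which cancels camera and head translation) -> selection of the
swallow event as the frame pair with the largest upward excursion of the
relative y coordinate -> an IoU/validity gate over the selected interval ->
pixel-to-millimeter calibration from a reference segment of known physical
length (e.g. a C3 or C4 vertebral-body diagonal measured on MRI) -> the
elevation displacement in mm.

With the image convention (y grows downward) elevation is a *decrease* of
the relative y coordinate: the "lowest point" frame has the largest rel_y
and the "highest point" frame the smallest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotations_io import AnnotationSet, StructureLabel, StructureMask, VideoMeta
from .errors import CalibrationError, EventError
from .evaluation import FrameIoU, match_detections

__all__ = [
    "TrackPoint",
    "MidpointTrack",
    "RelativeTrajectory",
    "Calibration",
    "SwallowEvent",
    "VelocityResult",
    "midpoint",
    "build_track",
    "relative_trajectory",
    "select_swallow_event",
    "gate_event",
    "calibration_from_reference",
    "elevation_mm",
    "elevation_velocity",
]


def midpoint(
    mask: StructureMask, meta: VideoMeta, mode: str = "centroid"
) -> tuple[float, float]:
    """Representative point of a structure mask, in pixel coordinates.

    ``centroid`` (default): mean of the set pixels' centers ``(c+0.5, r+0.5)``.
    ``bbox``: center of the axis-aligned bounding box of the set pixels,
    available for sensitivity analysis.
    """
    raster = mask.to_raster(meta)
    rows, cols = np.nonzero(raster)
    if rows.size == 0:
        raise EventError("cannot take the midpoint of an empty mask")
    if mode == "centroid":
        return (float(cols.mean()) + 0.5, float(rows.mean()) + 0.5)
    if mode == "bbox":
        return (
            (float(cols.min()) + float(cols.max())) / 2.0 + 0.5,
            (float(rows.min()) + float(rows.max())) / 2.0 + 0.5,
        )
    raise EventError(f"unknown midpoint mode {mode!r}; use 'centroid' or 'bbox'")


@dataclass(frozen=True)
class TrackPoint:
    frame_index: int
    tvc: Optional[tuple[float, float]] = None
    c1: Optional[tuple[float, float]] = None

    @property
    def valid(self) -> bool:
        return self.tvc is not None and self.c1 is not None


@dataclass
class MidpointTrack:
    """Per-frame TVC and C1 midpoints; a frame is valid iff both are present."""

    points: list[TrackPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


@dataclass
class RelativeTrajectory:
    """Per-frame TVC midpoint minus C1 midpoint; missing where the track is invalid."""

    frames: np.ndarray              # int frame indices, shape (n,)
    rel: np.ndarray                 # float (n, 2), NaN where missing
    valid: np.ndarray               # bool (n,)

    def rel_at(self, frame_index: int) -> tuple[float, float]:
        pos = int(np.flatnonzero(self.frames == frame_index)[0])
        if not self.valid[pos]:
            raise EventError(f"frame {frame_index} has no valid relative midpoint")
        return (float(self.rel[pos, 0]), float(self.rel[pos, 1]))

    def valid_between(self, lo: int, hi: int) -> bool:
        """True iff every frame index in [lo, hi] is present and valid."""
        wanted = set(range(lo, hi + 1))
        present = {int(f) for f, v in zip(self.frames, self.valid) if v}
        return wanted <= present


def build_track(pred: AnnotationSet, mode: str = "centroid") -> MidpointTrack:
    """Per-frame midpoints from an annotation set (predictions or ground truth).

    Multiple instances per label are resolved by :func:`match_detections`;
    a frame missing either structure is marked invalid.
    """
    points = []
    for frame in pred.frames:
        coords = {}
        for label in (StructureLabel.TVC, StructureLabel.C1_SPINOUS):
            m = match_detections(frame, label, pred.meta)
            coords[label] = midpoint(m, pred.meta, mode) if m is not None else None
        points.append(
            TrackPoint(frame.frame_index, tvc=coords[StructureLabel.TVC], c1=coords[StructureLabel.C1_SPINOUS])
        )
    return MidpointTrack(points=points)


def relative_trajectory(track: MidpointTrack) -> RelativeTrajectory:
    """Componentwise TVC − C1 for valid frames; NaN elsewhere."""
    frames = np.array([p.frame_index for p in track.points], dtype=int)
    rel = np.full((len(track.points), 2), np.nan)
    valid = np.zeros(len(track.points), dtype=bool)
    for i, p in enumerate(track.points):
        if p.valid:
            rel[i] = (p.tvc[0] - p.c1[0], p.tvc[1] - p.c1[1])
            valid[i] = True
    return RelativeTrajectory(frames=frames, rel=rel, valid=valid)


def select_swallow_event(traj: RelativeTrajectory) -> Optional[tuple[int, int]]:
    """Pick the swallow event as the longest upward trajectory of rel_y.

    Among all valid frame pairs (i, j) with i < j, returns the pair
    maximizing ``rel_y(i) − rel_y(j)`` — the largest upward excursion under
    the y-down convention, i.e. the interval from the larynx's lowest resting
    position to its highest point.  Ties are broken by the smallest i, then
    the smallest j.  Returns ``None`` when the maximum excursion is <= 0 (the
    larynx never rises).  Raises :class:`EventError` with fewer than 2 valid
    frames.

    Single left-to-right scan: for each candidate peak j the best partner is
    the earliest prefix maximum of rel_y, which realizes every tie-break.
    """
    idx = traj.frames[traj.valid]
    y = traj.rel[traj.valid, 1]
    if idx.size < 2:
        raise EventError(f"need >= 2 valid frames to select a swallow event, got {idx.size}")

    best_excursion = -math.inf
    best_pair: Optional[tuple[int, int]] = None
    prefix_max_y = y[0]
    prefix_arg = int(idx[0])
    for k in range(1, idx.size):
        excursion = prefix_max_y - y[k]
        if excursion > best_excursion or (
            excursion == best_excursion and best_pair is not None and prefix_arg < best_pair[0]
        ):
            best_excursion = excursion
            best_pair = (prefix_arg, int(idx[k]))
        if y[k] > prefix_max_y:  # strict: keep the earliest maximum
            prefix_max_y = y[k]
            prefix_arg = int(idx[k])
    if best_excursion <= 0:
        return None
    return best_pair


def gate_event(
    event: tuple[int, int],
    traj: RelativeTrajectory,
    iou_series: Optional[Sequence[FrameIoU]] = None,
    threshold: float = 0.3,
) -> bool:
    """Validity gate over the selected interval.

    True iff every frame in ``[frame_low, frame_peak]`` has a valid relative
    midpoint AND — when a ground-truth IoU series for the TVC is supplied —
    a TVC IoU at or above ``threshold``.  Without ground truth, validity
    alone decides.
    """
    lo, hi = event
    if not traj.valid_between(lo, hi):
        return False
    if iou_series is not None:
        by_frame = {
            r.frame_index: r.iou
            for r in iou_series
            if r.label == StructureLabel.TVC
        }
        for f in range(lo, hi + 1):
            value = by_frame.get(f)
            if value is None or value < threshold:
                return False
    return True


@dataclass(frozen=True)
class Calibration:
    """mm-per-pixel conversion factors per image axis."""

    cf_x: float
    cf_y: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.cf_x <= 0 or self.cf_y <= 0:
            raise CalibrationError(f"conversion factors must be positive, got ({self.cf_x}, {self.cf_y})")


def calibration_from_reference(
    ref_x: Optional[tuple[float, float]] = None,
    ref_y: Optional[tuple[float, float]] = None,
    provenance: str = "",
) -> Calibration:
    """Build a calibration from reference segments ``(pixel_length, known_mm)``.

    One factor per axis; passing a single reference applies it isotropically.
    In the intended workflow the references are the diagonal lengths of the
    C3 and C4 vertebral bodies measured in pixels on the fluoroscopy frame
    and in mm on the same patient's MRI.
    """
    if ref_x is None and ref_y is None:
        raise CalibrationError("at least one reference segment is required")

    def factor(ref):
        px, mm = ref
        if px <= 0 or mm <= 0:
            raise CalibrationError(f"reference lengths must be positive, got {px} px / {mm} mm")
        return mm / px

    cf_x = factor(ref_x) if ref_x is not None else factor(ref_y)
    cf_y = factor(ref_y) if ref_y is not None else factor(ref_x)
    return Calibration(cf_x=cf_x, cf_y=cf_y, provenance=provenance)


@dataclass
class SwallowEvent:
    """A measured swallow: the lowest-point/highest-point frame pair and displacement."""

    frame_low: int
    frame_peak: int
    delta_px: tuple[float, float]
    displacement_px: float
    displacement_mm: float
    vertical_mm: float
    gate_passed: bool

    def __post_init__(self) -> None:
        if self.frame_low >= self.frame_peak:
            raise EventError(f"frame_low {self.frame_low} must precede frame_peak {self.frame_peak}")

    def to_dict(self) -> dict:
        return {
            "frame_low": self.frame_low,
            "frame_peak": self.frame_peak,
            "delta_px": list(self.delta_px),
            "displacement_px": self.displacement_px,
            "displacement_mm": self.displacement_mm,
            "vertical_mm": self.vertical_mm,
            "gate_passed": self.gate_passed,
        }


def elevation_mm(
    traj: RelativeTrajectory,
    event: tuple[int, int],
    calib: Calibration,
    gate_passed: bool = True,
    force: bool = False,
) -> SwallowEvent:
    """Calibrated elevation displacement between the event's two frames.

    Let (Δx, Δy) = rel(frame_peak) − rel(frame_low) in pixels.  The reported
    displacement is the two-axis calibrated Euclidean norm
    ``sqrt((cf_x·Δx)² + (cf_y·Δy)²)``; the pure vertical component
    ``cf_y·|Δy|`` is reported alongside.  Refuses ungated events unless
    ``force`` is set.
    """
    if not gate_passed and not force:
        raise EventError("event failed the validity/IoU gate; pass force=True to measure anyway")
    lo, hi = event
    rel_lo = traj.rel_at(lo)
    rel_hi = traj.rel_at(hi)
    dx = rel_hi[0] - rel_lo[0]
    dy = rel_hi[1] - rel_lo[1]
    disp_mm = math.hypot(calib.cf_x * dx, calib.cf_y * dy)
    return SwallowEvent(
        frame_low=lo,
        frame_peak=hi,
        delta_px=(dx, dy),
        displacement_px=math.hypot(dx, dy),
        displacement_mm=disp_mm,
        vertical_mm=calib.cf_y * abs(dy),
        gate_passed=gate_passed,
    )


@dataclass(frozen=True)
class VelocityResult:
    mean_mm_s: float
    peak_mm_s: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def elevation_velocity(
    traj: RelativeTrajectory,
    event: SwallowEvent,
    calib: Calibration,
    fps: float,
) -> VelocityResult:
    """Mean and peak elevation velocity over the event interval.

    Mean velocity is total displacement over the interval duration; peak
    velocity is the largest single-frame-step calibrated displacement times
    the frame rate.
    """
    if fps <= 0:
        raise EventError(f"fps must be positive, got {fps}")
    n_steps = event.frame_peak - event.frame_low
    if n_steps <= 0:
        raise EventError("zero-length event interval")
    mean_v = event.displacement_mm / (n_steps / fps)

    peak_step = 0.0
    prev = traj.rel_at(event.frame_low)
    for f in range(event.frame_low + 1, event.frame_peak + 1):
        cur = traj.rel_at(f)
        step = math.hypot(calib.cf_x * (cur[0] - prev[0]), calib.cf_y * (cur[1] - prev[1]))
        peak_step = max(peak_step, step)
        prev = cur
    return VelocityResult(mean_mm_s=mean_v, peak_mm_s=peak_step * fps)


def write_measurement_json(
    path: str | Path,
    event: Optional[SwallowEvent],
    velocity: Optional[VelocityResult] = None,
    calib: Optional[Calibration] = None,
    extra: Optional[dict] = None,
) -> None:
    """Assemble the measurement report (status ``no_event`` when none was found)."""
    doc: dict = {"status": "ok" if event is not None else "no_event"}
    if event is not None:
        doc["event"] = event.to_dict()
    if velocity is not None:
        doc["velocity"] = velocity.to_dict()
    if calib is not None:
        doc["calibration"] = {
            "cf_x_mm_per_px": calib.cf_x,
            "cf_y_mm_per_px": calib.cf_y,
            "provenance": calib.provenance,
        }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
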