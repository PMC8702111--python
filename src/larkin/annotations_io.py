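"""Data model and I/O for per-frame VFSS structure annotations.

A lateral-view videofluoroscopic swallowing study (VFSS) clip is annotated
frame by frame with up to three structures, each a closed curve: the thyroid
cartilage + vocal fold complex (TVC), the C1 spinous process (the static
reference used to cancel camera/head translation) and the anterior hyoid
margin / airway column.  This module defines the in-memory containers
(:class:`StructureMask`, :class:`FrameAnnotation`, :class:`AnnotationSet`),
polygon rasterization with exact pixel-membership semantics, and the
COCO-flavoured JSON + PNG-label-map + trajectory-CSV file formats.

Coordinate convention (image convention): 0-based pixel indices, ``x`` is the
column increasing rightward, ``y`` is the row increasing downward.  Laryngeal
elevation therefore corresponds to *decreasing* y.  The pixel at row ``r``,
column ``c`` has its center at ``(c + 0.5, r + 0.5)``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationParseError, InvalidAnnotationError

__all__ = [
    "VideoMeta",
    "StructureLabel",
    "StructureMask",
    "FrameAnnotation",
    "AnnotationSet",
    "rasterize_polygon",
    "read_annotations",
    "write_annotations",
    "read_label_maps",
    "write_label_maps",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "TRAJECTORY_HEADER",
]

TRAJECTORY_HEADER = ["frame", "tvc_x", "tvc_y", "c1_x", "c1_y", "rel_x", "rel_y", "valid"]


@dataclass(frozen=True)
class VideoMeta:
    """Frame geometry and rate of a VFSS clip.  Defaults: 640x480 at 30 fps."""

    width: int = 640
    height: int = 480
    fps: float = 30.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidAnnotationError(f"non-positive frame size {self.width}x{self.height}")
        if self.fps <= 0:
            raise InvalidAnnotationError(f"non-positive fps {self.fps}")
        if self.n_frames < 1:
            raise InvalidAnnotationError(f"n_frames must be >= 1, got {self.n_frames}")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as (rows, cols)."""
        return (self.height, self.width)


class StructureLabel(str, enum.Enum):
    """The three annotated anatomical structures."""

    TVC = "tvc"
    C1_SPINOUS = "c1_spinous"
    HYOID_AIRWAY = "hyoid_airway"

    @classmethod
    def parse(cls, value: str) -> "StructureLabel":
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise AnnotationParseError(
                f"unknown structure label {value!r}; expected one of: {valid}"
            ) from None


# fixed category ids for the JSON dialect
_CATEGORY_IDS = {StructureLabel.TVC: 1, StructureLabel.C1_SPINOUS: 2, StructureLabel.HYOID_AIRWAY: 3}
_CATEGORY_BY_ID = {v: k for k, v in _CATEGORY_IDS.items()}
# PNG label-map pixel values
LABELMAP_VALUES = {StructureLabel.TVC: 1, StructureLabel.C1_SPINOUS: 2, StructureLabel.HYOID_AIRWAY: 3}


def _point_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd test with boundary points counted as inside.

    ``px``, ``py`` are flat arrays of query coordinates; ``poly`` is (n, 2).
    """
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    tol = 1e-9
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        # ray-crossing parity: horizontal ray toward +x
        cond = (y1 > py) != (y2 > py)
        if np.any(cond):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (px < xint)
        # boundary membership: collinear and within the segment bbox
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        seg_len = np.hypot(x2 - x1, y2 - y1)
        near = np.abs(cross) <= tol * max(seg_len, 1.0)
        within = (
            (px >= min(x1, x2) - tol)
            & (px <= max(x1, x2) + tol)
            & (py >= min(y1, y2) - tol)
            & (py <= max(y1, y2) + tol)
        )
        on_edge |= near & within
    return inside | on_edge


def rasterize_polygon(polygon: Sequence[Sequence[float]], meta: VideoMeta) -> np.ndarray:
    """Rasterize a closed polygon to a boolean mask of shape ``meta.shape``.

    A pixel is set iff its center ``(c + 0.5, r + 0.5)`` lies inside the
    closed polygon under the even-odd rule; centers exactly on the boundary
    count as inside.  Vertices outside the frame are clipped to its edges.

    Raises
    ------
    InvalidAnnotationError
        If the polygon has fewer than 3 vertices.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise InvalidAnnotationError(
            f"polygon must be an (n>=3, 2) vertex list, got shape {poly.shape}"
        )
    poly = poly.copy()
    poly[:, 0] = np.clip(poly[:, 0], 0.0, float(meta.width))
    poly[:, 1] = np.clip(poly[:, 1], 0.0, float(meta.height))

    out = np.zeros(meta.shape, dtype=bool)
    c0 = max(int(np.floor(poly[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(poly[:, 0].max() + 0.5)), meta.width)
    r0 = max(int(np.floor(poly[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(poly[:, 1].max() + 0.5)), meta.height)
    if c0 >= c1 or r0 >= r1:
        return out
    xs = np.arange(c0, c1, dtype=float) + 0.5
    ys = np.arange(r0, r1, dtype=float) + 0.5
    X, Y = np.meshgrid(xs, ys)
    out[r0:r1, c0:c1] = _point_in_polygon(X.ravel(), Y.ravel(), poly).reshape(X.shape)
    return out


@dataclass
class StructureMask:
    """One labeled segmented structure in one frame.

    At least one of ``polygon`` (ordered (x, y) vertices, pixel coordinates)
    and ``raster`` (boolean height x width mask) must be present; the raster
    is derived lazily from the polygon when needed.  ``score`` is the
    detector confidence for predicted instances.
    """

    label: StructureLabel
    polygon: Optional[np.ndarray] = None
    raster: Optional[np.ndarray] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.polygon is None and self.raster is None:
            raise InvalidAnnotationError("StructureMask needs a polygon or a raster")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
                raise InvalidAnnotationError(
                    f"polygon for {self.label.value} must have >= 3 (x, y) vertices"
                )
        if self.raster is not None:
            self.raster = np.asarray(self.raster, dtype=bool)
            if not self.raster.any():
                raise InvalidAnnotationError(f"raster for {self.label.value} has no set pixel")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InvalidAnnotationError(f"score {self.score} outside [0, 1]")

    def to_raster(self, meta: VideoMeta) -> np.ndarray:
        """Boolean mask of shape ``meta.shape`` (rasterizes the polygon on demand)."""
        if self.raster is not None:
            if self.raster.shape != meta.shape:
                raise InvalidAnnotationError(
                    f"raster shape {self.raster.shape} does not match video {meta.shape}"
                )
            return self.raster
        self.raster = rasterize_polygon(self.polygon, meta)
        if not self.raster.any():
            raise InvalidAnnotationError(
                f"polygon for {self.label.value} rasterizes to an empty mask"
            )
        return self.raster

    def area(self, meta: VideoMeta) -> int:
        return int(self.to_raster(meta).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureMask):
            return NotImplemented
        if self.label != other.label or self.score != other.score:
            return False
        if (self.polygon is None) != (other.polygon is None):
            return False
        if self.polygon is not None and not np.array_equal(self.polygon, other.polygon):
            return False
        a, b = self.raster, other.raster
        if self.polygon is None:  # raster is the sole geometry: must match exactly
            return a is not None and b is not None and np.array_equal(a, b)
        return True


@dataclass
class FrameAnnotation:
    """All structure instances of one frame (0-based ``frame_index``)."""

    frame_index: int
    structures: list[StructureMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InvalidAnnotationError(f"negative frame index {self.frame_index}")

    def instances(self, label: StructureLabel) -> list[StructureMask]:
        return [s for s in self.structures if s.label == label]


@dataclass
class AnnotationSet:
    """A full clip's annotations: metadata plus frames sorted by index.

    ``kind`` distinguishes manual ground truth (at most one instance per label
    per frame) from model predictions (multiple instances allowed; resolution
    is the evaluation module's job).
    """

    meta: VideoMeta
    frames: list[FrameAnnotation]
    kind: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.kind not in ("ground_truth", "prediction"):
            raise InvalidAnnotationError(f"kind must be ground_truth or prediction, got {self.kind!r}")
        self.frames = sorted(self.frames, key=lambda f: f.frame_index)
        indices = [f.frame_index for f in self.frames]
        if len(set(indices)) != len(indices):
            raise InvalidAnnotationError("duplicate frame indices in AnnotationSet")
        if self.kind == "ground_truth":
            for f in self.frames:
                for lab in StructureLabel:
                    if len(f.instances(lab)) > 1:
                        raise InvalidAnnotationError(
                            f"frame {f.frame_index}: multiple ground-truth instances of {lab.value}"
                        )

    def frame(self, index: int) -> Optional[FrameAnnotation]:
        for f in self.frames:
            if f.frame_index == index:
                return f
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.kind == other.kind
            and len(self.frames) == len(other.frames)
            and all(
                a.frame_index == b.frame_index and a.structures == b.structures
                for a, b in zip(self.frames, other.frames)
            )
        )


# ---------------------------------------------------------------------------
# COCO-flavoured JSON dialect
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> dict:
    """COCO-style uncompressed RLE: column-major run lengths starting with 0s."""
    flat = np.asfortranarray(mask).ravel(order="F").astype(np.uint8)
    # run-length encode; counts alternate background/foreground starting at 0
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], change, [flat.size])))
    counts = runs.tolist()
    if flat[0] == 1:
        counts = [0] + counts
    return {"counts": counts, "size": [int(mask.shape[0]), int(mask.shape[1])]}


def _rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != h * w:
        raise AnnotationParseError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Serialize deterministically (sorted frames/labels; stable float repr).

    Repeated writes of an equal set produce byte-identical files.
    """
    images = []
    annotations = []
    ann_id = 1
    for img_id, frame in enumerate(aset.frames, start=1):
        images.append(
            {
                "id": img_id,
                "frame_index": frame.frame_index,
                "width": aset.meta.width,
                "height": aset.meta.height,
                "file_name": f"frame_{frame.frame_index:06d}.png",
            }
        )
        ordered = sorted(
            frame.structures,
            key=lambda s: _CATEGORY_IDS[s.label],
        )
        for s in ordered:
            entry: dict = {"id": ann_id, "image_id": img_id, "category_id": _CATEGORY_IDS[s.label]}
            if s.polygon is not None:
                entry["segmentation"] = [float(v) for v in s.polygon.ravel()]
            else:
                entry["segmentation"] = _rle_encode(s.raster)
            if s.score is not None:
                entry["score"] = float(s.score)
            annotations.append(entry)
            ann_id += 1
    doc = {
        "info": {
            "width": aset.meta.width,
            "height": aset.meta.height,
            "fps": aset.meta.fps,
            "n_frames": aset.meta.n_frames,
            "kind": aset.kind,
        },
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": cid, "name": lab.value} for lab, cid in sorted(_CATEGORY_IDS.items(), key=lambda kv: kv[1])
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_annotations(path: str | Path, kind: Optional[str] = None) -> AnnotationSet:
    """Read the COCO-flavoured JSON dialect written by :func:`write_annotations`.

    ``kind`` overrides the file's recorded kind (``ground_truth``/``prediction``).
    Malformed content raises :class:`AnnotationParseError` naming the frame
    and field at fault.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationParseError(f"cannot read annotation file {path}: {exc}") from exc

    info = doc.get("info", {})
    meta = VideoMeta(
        width=int(info.get("width", 640)),
        height=int(info.get("height", 480)),
        fps=float(info.get("fps", 30.0)),
        n_frames=int(info.get("n_frames", max(1, len(doc.get("images", []))))),
    )
    label_by_cat: dict[int, StructureLabel] = {}
    for cat in doc.get("categories", []):
        label_by_cat[int(cat["id"])] = StructureLabel.parse(cat["name"])

    frames_by_img: dict[int, FrameAnnotation] = {}
    for img in doc.get("images", []):
        if "frame_index" not in img:
            raise AnnotationParseError(f"image id {img.get('id')}: missing frame_index")
        frames_by_img[int(img["id"])] = FrameAnnotation(int(img["frame_index"]))

    for ann in doc.get("annotations", []):
        img_id = int(ann["image_id"])
        if img_id not in frames_by_img:
            raise AnnotationParseError(f"annotation {ann.get('id')}: unknown image_id {img_id}")
        frame = frames_by_img[img_id]
        cat_id = int(ann["category_id"])
        if cat_id not in label_by_cat:
            raise AnnotationParseError(
                f"frame {frame.frame_index}: unknown category_id {cat_id}"
            )
        label = label_by_cat[cat_id]
        seg = ann.get("segmentation")
        try:
            if isinstance(seg, dict):
                mask = StructureMask(label, raster=_rle_decode(seg), score=ann.get("score"))
            elif isinstance(seg, list):
                flat = np.asarray(seg, dtype=float)
                if flat.size < 6 or flat.size % 2:
                    raise InvalidAnnotationError(
                        f"flat polygon needs an even number >= 6 of coordinates, got {flat.size}"
                    )
                mask = StructureMask(label, polygon=flat.reshape(-1, 2), score=ann.get("score"))
            else:
                raise InvalidAnnotationError(f"unsupported segmentation type {type(seg).__name__}")
        except InvalidAnnotationError as exc:
            raise AnnotationParseError(
                f"frame {frame.frame_index}, label {label.value}: {exc}"
            ) from exc
        frame.structures.append(mask)

    return AnnotationSet(
        meta=meta,
        frames=list(frames_by_img.values()),
        kind=kind or info.get("kind", "ground_truth"),
    )


# ---------------------------------------------------------------------------
# PNG label maps (raster alternative)
# ---------------------------------------------------------------------------

def write_label_maps(aset: AnnotationSet, directory: str | Path) -> None:
    """Write one PNG label map per frame (0=background, 1=TVC, 2=C1, 3=hyoid).

    Only ground-truth sets (single instance per label) can be written losslessly.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in aset.frames:
        canvas = np.zeros(aset.meta.shape, dtype=np.uint8)
        for s in frame.structures:
            canvas[s.to_raster(aset.meta)] = LABELMAP_VALUES[s.label]
        iio.imwrite(directory / f"frame_{frame.frame_index:06d}.png", canvas)


def read_label_maps(directory: str | Path, meta: Optional[VideoMeta] = None) -> AnnotationSet:
    """Read ``frame_%06d.png`` label maps into a ground-truth AnnotationSet."""
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise AnnotationParseError(f"no frame_*.png label maps in {directory}")
    frames = []
    shape = None
    for p in paths:
        idx = int(p.stem.split("_")[1])
        canvas = np.asarray(iio.imread(p))
        shape = canvas.shape
        structures = []
        for lab, value in LABELMAP_VALUES.items():
            raster = canvas == value
            if raster.any():
                structures.append(StructureMask(lab, raster=raster))
        frames.append(FrameAnnotation(idx, structures))
    if meta is None:
        meta = VideoMeta(width=shape[1], height=shape[0], n_frames=len(frames))
    return AnnotationSet(meta=meta, frames=frames, kind="ground_truth")


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectory_csv(track, path: str | Path) -> None:
    """Persist a midpoint track as CSV (one row per frame, empty fields = missing).

    Header: ``frame,tvc_x,tvc_y,c1_x,c1_y,rel_x,rel_y,valid``.
    """
    rows = []
    for pt in track.points:
        tvc, c1 = pt.tvc, pt.c1
        rel = (tvc[0] - c1[0], tvc[1] - c1[1]) if pt.valid else (None, None)
        rows.append(
            {
                "frame": pt.frame_index,
                "tvc_x": tvc[0] if tvc is not None else None,
                "tvc_y": tvc[1] if tvc is not None else None,
                "c1_x": c1[0] if c1 is not None else None,
                "c1_y": c1[1] if c1 is not None else None,
                "rel_x": rel[0],
                "rel_y": rel[1],
                "valid": "true" if pt.valid else "false",
            }
        )
    df = pd.DataFrame(rows, columns=TRAJECTORY_HEADER)
    df.to_csv(path, index=False, na_rep="", float_format=None)


def read_trajectory_csv(path: str | Path):
    """Read a trajectory CSV back into a :class:`larkin.kinematics.MidpointTrack`."""
    from .kinematics import MidpointTrack, TrackPoint

    df = pd.read_csv(path)
    points = []
    for _, row in df.iterrows():
        tvc = None if pd.isna(row["tvc_x"]) else (float(row["tvc_x"]), float(row["tvc_y"]))
        c1 = None if pd.isna(row["c1_x"]) else (float(row["c1_x"]), float(row["c1_y"]))
        points.append(TrackPoint(int(row["frame"]), tvc=tvc, c1=c1))
    return MidpointTrack(points=points)
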