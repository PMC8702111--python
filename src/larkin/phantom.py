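"""Synthetic VFSS phantom: sequences with exact ground truth, mask
degradation, the training-time augmentation recipe, and a classical
threshold segmenter that plays the role of a learned instance segmenter at
desk scale.

The phantom renders a lateral-view-like grayscale sequence containing a
static C1 blob and a TVC blob that rises and falls once over roughly one
second — the duration of the swallowing reflex.  Geometry is elliptical on
purpose: the downstream measurement consumes only masks and centroids, so
anatomical shape realism is irrelevant to its correctness.  Every stochastic
operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .annotations_io import (
    AnnotationSet,
    FrameAnnotation,
    StructureLabel,
    StructureMask,
    VideoMeta,
)
from .errors import DataError, PhantomError

__all__ = [
    "PhantomSpec",
    "PhantomSequence",
    "AugmentParams",
    "SegmenterConfig",
    "generate_phantom",
    "degrade_mask",
    "augment_frame",
    "apply_augment",
    "threshold_segmenter",
    "segmenter_config_for",
    "write_phantom",
]

BACKGROUND_INTENSITY = 30.0
STRUCTURE_INTENSITY = 180.0


@dataclass(frozen=True)
class PhantomSpec:
    """Kinematic and rendering parameters of a synthetic swallow sequence.

    Defaults emulate the clip format of the intended use case (640x480 at
    30 fps) with a single ~1 s swallow: a raised-cosine rise of 15 frames,
    a 5-frame hold at the top, and a 15-frame fall, with an upward excursion
    of 70 px.  ``lateral_shift_px`` adds a horizontal component to the TVC
    excursion (0 by default: elevation is predominantly vertical in the
    lateral view).  Intensities are 30 (background) and 180 (structures)
    before Gaussian pixel noise (``noise_sd``) and blur (``blur_sigma``).
    """

    meta: VideoMeta = field(default_factory=lambda: VideoMeta(640, 480, 30.0, 60))
    c1_center: tuple[float, float] = (320.0, 120.0)
    c1_axes: tuple[float, float] = (26.0, 18.0)
    tvc_rest_center: tuple[float, float] = (300.0, 360.0)
    tvc_axes: tuple[float, float] = (46.0, 30.0)
    amplitude_px: float = 70.0
    rise_frames: int = 15
    hold_frames: int = 5
    fall_frames: int = 15
    lateral_shift_px: float = 0.0
    noise_sd: float = 10.0
    blur_sigma: float = 1.0
    render_hyoid: bool = False
    hyoid_center: tuple[float, float] = (180.0, 260.0)
    hyoid_axes: tuple[float, float] = (18.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_px <= 0:
            raise PhantomError(f"amplitude_px must be positive, got {self.amplitude_px}")
        if min(self.rise_frames, self.fall_frames) < 1 or self.hold_frames < 0:
            raise PhantomError("rise/fall must be >= 1 frame and hold >= 0")
        if self.rise_frames + self.hold_frames + self.fall_frames > self.meta.n_frames:
            raise PhantomError(
                f"motion ({self.rise_frames}+{self.hold_frames}+{self.fall_frames} frames) "
                f"does not fit in {self.meta.n_frames} frames"
            )

    def profile(self, t: int) -> float:
        """Normalized elevation g(t) in [0, 1]: raised-cosine rise, hold, fall."""
        r, h, f = self.rise_frames, self.hold_frames, self.fall_frames
        if t <= 0:
            return 0.0
        if t < r:
            return 0.5 * (1.0 - np.cos(np.pi * t / r))
        if t <= r + h:
            return 1.0
        if t < r + h + f:
            return 0.5 * (1.0 + np.cos(np.pi * (t - r - h) / f))
        return 0.0

    def tvc_center(self, t: int) -> tuple[float, float]:
        g = self.profile(t)
        return (
            self.tvc_rest_center[0] + self.lateral_shift_px * g,
            self.tvc_rest_center[1] - self.amplitude_px * g,
        )

    @property
    def true_event(self) -> tuple[int, int]:
        """Lowest-point / highest-point frame pair (start, first plateau frame)."""
        return (0, self.rise_frames)

    @property
    def true_displacement_px(self) -> float:
        return float(np.hypot(self.lateral_shift_px, self.amplitude_px))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["meta"] = {
            "width": self.meta.width,
            "height": self.meta.height,
            "fps": self.meta.fps,
            "n_frames": self.meta.n_frames,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "meta" in d:
            d["meta"] = VideoMeta(**d["meta"])
        for key in ("c1_center", "c1_axes", "tvc_rest_center", "tvc_axes", "hyoid_center", "hyoid_axes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomSequence:
    """Rendered frames plus exact ground truth and true kinematics."""

    frames: list[np.ndarray]          # uint8 grayscale, height x width
    gt: AnnotationSet
    true_event: tuple[int, int]
    true_displacement_px: float
    spec: PhantomSpec


def _ellipse_mask(
    center: tuple[float, float], axes: tuple[float, float], meta: VideoMeta
) -> np.ndarray:
    """Pixels whose centers fall inside the ellipse."""
    cx, cy = center
    a, b = axes
    xs = np.arange(meta.width, dtype=float) + 0.5
    ys = np.arange(meta.height, dtype=float) + 0.5
    X, Y = np.meshgrid(xs, ys)
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0


def _check_bounds(center, axes, meta: VideoMeta, t: int, name: str) -> None:
    cx, cy = center
    a, b = axes
    if cx - a < 0 or cx + a > meta.width or cy - b < 0 or cy + b > meta.height:
        raise PhantomError(f"{name} leaves the frame at frame {t} (center {center}, axes {axes})")


def generate_phantom(spec: PhantomSpec) -> PhantomSequence:
    """Render the phantom sequence described by ``spec``.

    Ground-truth masks are the exact elliptical supports before noise and
    blur are applied to the image.  All randomness comes from ``spec.seed``;
    identical specs give byte-identical frames.
    """
    meta = spec.meta
    rng = np.random.default_rng(spec.seed)
    c1_mask = _ellipse_mask(spec.c1_center, spec.c1_axes, meta)
    _check_bounds(spec.c1_center, spec.c1_axes, meta, 0, "C1 blob")
    hyoid_mask = (
        _ellipse_mask(spec.hyoid_center, spec.hyoid_axes, meta) if spec.render_hyoid else None
    )

    frames: list[np.ndarray] = []
    gt_frames: list[FrameAnnotation] = []
    for t in range(meta.n_frames):
        tvc_center = spec.tvc_center(t)
        _check_bounds(tvc_center, spec.tvc_axes, meta, t, "TVC blob")
        tvc_mask = _ellipse_mask(tvc_center, spec.tvc_axes, meta)

        img = np.full(meta.shape, BACKGROUND_INTENSITY)
        img[c1_mask] = STRUCTURE_INTENSITY
        img[tvc_mask] = STRUCTURE_INTENSITY
        structures = [
            StructureMask(StructureLabel.TVC, raster=tvc_mask),
            StructureMask(StructureLabel.C1_SPINOUS, raster=c1_mask.copy()),
        ]
        if hyoid_mask is not None:
            img[hyoid_mask] = STRUCTURE_INTENSITY
            structures.append(StructureMask(StructureLabel.HYOID_AIRWAY, raster=hyoid_mask.copy()))

        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma)
        frames.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
        gt_frames.append(FrameAnnotation(t, structures))

    gt = AnnotationSet(meta=meta, frames=gt_frames, kind="ground_truth")
    return PhantomSequence(
        frames=frames,
        gt=gt,
        true_event=spec.true_event,
        true_displacement_px=spec.true_displacement_px,
        spec=spec,
    )


_SHIFT_DIRECTIONS = [(1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def degrade_mask(
    mask: StructureMask,
    target_iou: float,
    mode: str = "shift",
    seed: int = 0,
    meta: Optional[VideoMeta] = None,
    tolerance: float = 0.05,
) -> StructureMask:
    """Perturb a mask so its IoU with the original lands near ``target_iou``.

    ``mode`` is one of ``shift`` (translate along a seed-chosen direction),
    ``dilate`` or ``erode`` (morphological, growing iteration count).  The
    perturbation magnitude is found by monotone search: IoU with the original
    decreases as the magnitude grows, so the search stops at the first
    magnitude whose IoU drops to/below the target and keeps whichever of the
    last two magnitudes is closer.  For the nested morphological modes the
    final step is fractional: when two whole iterations bracket the target,
    a seeded subset of the boundary ring between them is toggled so the pixel
    count — and hence the IoU, which for nested masks is a pure area ratio —
    lands on the target.  Raises :class:`DataError` when the target cannot
    be approached within ``tolerance`` (e.g. erosion exhausts the mask
    first).
    """
    from .evaluation import iou as _iou

    if not (0.0 < target_iou <= 1.0):
        raise DataError(f"target_iou must be in (0, 1], got {target_iou}")
    if meta is None:
        if mask.raster is None:
            raise DataError("degrade_mask needs a raster mask or an explicit VideoMeta")
        meta = VideoMeta(width=mask.raster.shape[1], height=mask.raster.shape[0])
    original = mask.to_raster(meta)
    if target_iou == 1.0:
        return StructureMask(mask.label, raster=original.copy(), score=mask.score)

    if mode not in ("shift", "dilate", "erode"):
        raise DataError(f"unknown degradation mode {mode!r}")
    rng = np.random.default_rng(seed)

    def search(perturb) -> Optional[tuple[float, np.ndarray]]:
        found: Optional[tuple[float, np.ndarray]] = None
        prev_candidate = original
        for magnitude in range(1, max(original.shape) * 2 + 1):
            candidate = perturb(magnitude)
            if not candidate.any():
                break
            value = _iou(original, candidate)
            if found is None or abs(value - target_iou) < abs(found[0] - target_iou):
                found = (value, candidate)
            if value <= target_iou:
                if mode in ("dilate", "erode") and abs(value - target_iou) > tolerance:
                    refined = _fractional_morph_step(
                        original, prev_candidate, candidate, target_iou, mode, rng
                    )
                    if refined is not None:
                        found = (_iou(original, refined), refined)
                break
            prev_candidate = candidate
        return found

    best: Optional[tuple[float, np.ndarray]] = None
    if mode == "shift":
        # the first step along a direction bounds that direction's granularity;
        # try directions in a seeded order until one lands within tolerance
        for dy, dx in rng.permutation(_SHIFT_DIRECTIONS):
            found = search(lambda m: _shift_mask(original, int(dy) * m, int(dx) * m))
            if found is not None and (
                best is None or abs(found[0] - target_iou) < abs(best[0] - target_iou)
            ):
                best = found
            if best is not None and abs(best[0] - target_iou) <= tolerance:
                break
    else:
        op = ndimage.binary_dilation if mode == "dilate" else ndimage.binary_erosion
        best = search(lambda m: op(original, iterations=m))

    if best is None or abs(best[0] - target_iou) > tolerance:
        achieved = None if best is None else round(best[0], 3)
        raise DataError(
            f"cannot degrade mask to IoU {target_iou} +/- {tolerance} by {mode} "
            f"(closest achieved: {achieved})"
        )
    return StructureMask(mask.label, raster=best[1], score=mask.score)


def _fractional_morph_step(
    original: np.ndarray,
    inner_bracket: np.ndarray,
    outer_bracket: np.ndarray,
    target_iou: float,
    mode: str,
    rng: np.random.Generator,
) -> Optional[np.ndarray]:
    """Toggle a seeded subset of the ring between two nested morphological
    iterates so the area ratio (= IoU against the original) hits the target.

    For erosion the degraded mask is a subset of the original, so
    IoU = |D| / |original|; for dilation a superset, so IoU = |original| / |D|.
    """
    area0 = int(np.count_nonzero(original))
    if mode == "erode":
        larger, smaller = inner_bracket, outer_bracket  # prev iterate contains next
        want = int(round(target_iou * area0))
    else:
        larger, smaller = outer_bracket, inner_bracket  # next iterate contains prev
        want = int(round(area0 / target_iou))
    n_small = int(np.count_nonzero(smaller))
    n_large = int(np.count_nonzero(larger))
    if not (n_small <= want <= n_large):
        return None
    ring = np.flatnonzero(larger.ravel() & ~smaller.ravel())
    keep = rng.permutation(ring)[: want - n_small]
    out = smaller.copy().ravel()
    out[keep] = True
    out = out.reshape(original.shape)
    return out if out.any() else None


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer-shift a boolean mask, cropping at the borders."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random training-time augmentation recipe.

    Defaults: rotation U(-30, 30) degrees, scale U(0.8, 1.2), shift
    U(-10%, 10%) of each dimension, horizontal flip with p = 0.5, optional
    Gaussian blur of the image only.  Applied in the fixed order
    flip -> rotate -> scale -> shift -> blur.
    """

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    scale: tuple[float, float] = (0.8, 1.2)
    shift_frac: tuple[float, float] = (-0.1, 0.1)
    flip_prob: float = 0.5
    blur_sigma: float = 0.0


def apply_augment(
    image: np.ndarray,
    gt_masks: list[StructureMask],
    *,
    flip: bool,
    angle_deg: float,
    scale: float,
    shift_px: tuple[float, float],
    blur_sigma: float = 0.0,
    meta: Optional[VideoMeta] = None,
) -> tuple[np.ndarray, list[StructureMask]]:
    """Deterministic core of :func:`augment_frame` with explicit draws.

    The image is warped with bilinear interpolation, masks with nearest
    neighbour so they stay binary; both receive the identical geometric
    transform.  Masks that end up empty (shifted out of frame) are dropped.
    """
    h, w = image.shape[:2]
    if meta is None:
        meta = VideoMeta(width=w, height=h)

    img = np.fliplr(image) if flip else image
    rasters = [np.fliplr(m.to_raster(meta)) if flip else m.to_raster(meta) for m in gt_masks]

    identity = angle_deg == 0.0 and scale == 1.0 and shift_px == (0.0, 0.0)
    if not identity:
        center = np.array([w / 2.0, h / 2.0])
        tform = (
            transform.AffineTransform(translation=-center)
            + transform.AffineTransform(rotation=np.deg2rad(angle_deg))
            + transform.AffineTransform(scale=scale)
            + transform.AffineTransform(translation=center)
            + transform.AffineTransform(translation=shift_px)
        )
        img = transform.warp(
            img.astype(float), tform.inverse, order=1, mode="constant",
            cval=float(np.min(img)), preserve_range=True,
        )
        rasters = [
            transform.warp(r.astype(float), tform.inverse, order=0, mode="constant", cval=0.0) > 0.5
            for r in rasters
        ]
    else:
        img = img.astype(float)

    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)

    out_masks = [
        StructureMask(m.label, raster=r, score=m.score)
        for m, r in zip(gt_masks, rasters)
        if r.any()
    ]
    if np.issubdtype(image.dtype, np.integer):
        img = np.clip(np.rint(img), np.iinfo(image.dtype).min, np.iinfo(image.dtype).max).astype(image.dtype)
    return img, out_masks


def augment_frame(
    image: np.ndarray,
    gt_masks: list[StructureMask],
    params: Optional[AugmentParams] = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[StructureMask]]:
    """Randomly augment one frame and its masks (all draws from ``seed``)."""
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    flip = bool(rng.random() < params.flip_prob)
    angle = float(rng.uniform(*params.rotation_deg))
    scale = float(rng.uniform(*params.scale))
    h, w = image.shape[:2]
    shift = (
        float(rng.uniform(*params.shift_frac)) * w,
        float(rng.uniform(*params.shift_frac)) * h,
    )
    return apply_augment(
        image,
        gt_masks,
        flip=flip,
        angle_deg=angle,
        scale=scale,
        shift_px=shift,
        blur_sigma=params.blur_sigma,
    )


@dataclass(frozen=True)
class SegmenterConfig:
    """Classical segmenter settings: binarization threshold, the search box
    (x0, y0, x1, y1) whose interior identifies the C1 component by centroid,
    and the minimum region area in pixels."""

    threshold: float = 105.0
    c1_box: tuple[float, float, float, float] = (0.0, 0.0, 640.0, 240.0)
    min_area: int = 50


def segmenter_config_for(spec: PhantomSpec, margin: float = 60.0) -> SegmenterConfig:
    """Segmenter config matched to a phantom spec (C1 box around its blob)."""
    cx, cy = spec.c1_center
    return SegmenterConfig(
        threshold=(BACKGROUND_INTENSITY + STRUCTURE_INTENSITY) / 2.0,
        c1_box=(cx - margin, cy - margin, cx + margin, cy + margin),
        min_area=50,
    )


def threshold_segmenter(
    frame: np.ndarray, config: SegmenterConfig, frame_index: int = 0
) -> FrameAnnotation:
    """Intensity-threshold instance segmenter (stand-in for a learned model).

    Binarizes the frame, extracts 8-connected components, and discards small
    regions.  The component whose centroid falls inside the C1 search box is
    labeled C1; the largest remaining component becomes the TVC.  The score
    is the region's mean intensity normalized to [0, 1].  Frames may
    legitimately yield no detections.
    """
    binary = np.asarray(frame, dtype=float) > config.threshold
    labeled = measure.label(binary, connectivity=2)
    regions = [r for r in measure.regionprops(labeled, intensity_image=np.asarray(frame, float))
               if r.area >= config.min_area]

    x0, y0, x1, y1 = config.c1_box
    c1_candidates = [
        r for r in regions
        if x0 <= r.centroid[1] <= x1 and y0 <= r.centroid[0] <= y1
    ]
    structures: list[StructureMask] = []
    c1_region = max(c1_candidates, key=lambda r: r.area, default=None)
    if c1_region is not None:
        structures.append(_region_to_mask(c1_region, labeled, StructureLabel.C1_SPINOUS))
    remaining = [r for r in regions if r is not c1_region]
    tvc_region = max(remaining, key=lambda r: r.area, default=None)
    if tvc_region is not None:
        structures.append(_region_to_mask(tvc_region, labeled, StructureLabel.TVC))
    return FrameAnnotation(frame_index, structures)


def _region_to_mask(region, labeled: np.ndarray, label: StructureLabel) -> StructureMask:
    raster = labeled == region.label
    score = float(np.clip(region.intensity_mean / 255.0, 0.0, 1.0))
    return StructureMask(label, raster=raster, score=score)


def write_phantom(seq: PhantomSequence, directory: str | Path) -> None:
    """Write frames (PNG), ground-truth JSON and truth.json to a directory."""
    import imageio.v3 as iio

    from .annotations_io import write_annotations

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"frame_{t:06d}.png", frame)
    write_annotations(seq.gt, directory / "gt.json")
    truth = {
        "true_event": list(seq.true_event),
        "true_displacement_px": seq.true_displacement_px,
        "spec": seq.spec.to_dict(),
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
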