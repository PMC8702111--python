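"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from larkin.annotations_io import (
    AnnotationSet,
    FrameAnnotation,
    StructureLabel,
    StructureMask,
    VideoMeta,
)
from larkin.phantom import PhantomSpec, generate_phantom

settings.register_profile("default", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never share code with larkin)
# ---------------------------------------------------------------------------

def iou_pixel_count_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive per-pixel IoU: loop every cell, count overlap and union."""
    inter = union = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            pa, pb = bool(a[r, c]), bool(b[r, c])
            if pa and pb:
                inter += 1
            if pa or pb:
                union += 1
    return inter / union


def best_excursion_pair_oracle(frames, rel_y):
    """Exhaustive O(n^2) search for the frame pair maximizing rel_y[i]-rel_y[j].

    Returns (frame_i, frame_j, excursion) for the lexicographically smallest
    maximizing pair, or None when the best excursion is <= 0.
    """
    best = None
    n = len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            exc = rel_y[i] - rel_y[j]
            if best is None or exc > best[2]:
                best = (frames[i], frames[j], exc)
    if best is None or best[2] <= 0:
        return None
    return best


def point_in_polygon_oracle(polygon):
    """Shapely-backed point membership test (boundary counts as inside)."""
    from shapely.geometry import Point, Polygon

    poly = Polygon(polygon)

    def contains(x: float, y: float) -> bool:
        return poly.intersects(Point(x, y))

    return contains


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def small_meta() -> VideoMeta:
    return VideoMeta(width=32, height=32, fps=30.0, n_frames=4)


@pytest.fixture()
def square_mask() -> np.ndarray:
    m = np.zeros((64, 64), dtype=bool)
    m[20:40, 20:40] = True
    return m


def make_gt_set(meta: VideoMeta, rasters_by_frame) -> AnnotationSet:
    """Build a ground-truth AnnotationSet from {frame: {label: raster}}."""
    frames = [
        FrameAnnotation(idx, [StructureMask(lab, raster=r) for lab, r in structures.items()])
        for idx, structures in rasters_by_frame.items()
    ]
    return AnnotationSet(meta=meta, frames=frames, kind="ground_truth")


@pytest.fixture(scope="session")
def default_phantom():
    """The default 640x480 phantom sequence (session-scoped: rendering 60
    frames with noise and blur is the most expensive fixture)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free phantom for exact-recovery checks."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, blur_sigma=0.0, seed=7))


@pytest.fixture()
def small_spec() -> PhantomSpec:
    """A quarter-scale phantom for fast CLI and I/O round trips."""
    return PhantomSpec(
        meta=VideoMeta(160, 120, 30.0, 24),
        c1_center=(80.0, 30.0),
        c1_axes=(8.0, 6.0),
        tvc_rest_center=(75.0, 95.0),
        tvc_axes=(12.0, 8.0),
        amplitude_px=40.0,
        rise_frames=8,
        hold_frames=2,
        fall_frames=8,
        noise_sd=5.0,
        blur_sigma=0.8,
        seed=3,
    )


def as_predictions(gt: AnnotationSet) -> AnnotationSet:
    """Relabel a ground-truth set as predictions (perfect-detector stand-in)."""
    return AnnotationSet(meta=gt.meta, frames=gt.frames, kind="prediction")
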