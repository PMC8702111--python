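"""Segmentation-quality metrics for VFSS structure masks.

The measurement chain only needs the larynx *found well enough to locate*,
not segmented perfectly, so detection validity uses a deliberately permissive
IoU cutoff of 0.3: a frame counts as a true positive when the structure is
detected with IoU >= 0.3, and as a false negative otherwise.  Recall is
TP / (TP + FN) over frames that carry ground truth for the label.

Mean IoU is reported two ways because a missed detection can either count as
IoU 0 or be excluded: ``iou_mean`` includes misses as 0 (the convention whose
reported ranges start at 0), ``iou_mean_detected`` excludes them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotations_io import AnnotationSet, FrameAnnotation, StructureLabel, StructureMask
from .errors import DataError

__all__ = [
    "FrameIoU",
    "LabelSummary",
    "EvaluationReport",
    "PeakComparison",
    "iou",
    "match_detections",
    "evaluate",
    "compare_peak_iou",
    "mask_bce_loss",
]

DEFAULT_IOU_THRESHOLD = 0.3


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary rasters.

    IoU = |A ∩ B| / |A ∪ B|, computed on pixel counts.  Symmetric.  Raises
    :class:`DataError` on shape mismatch or when both masks are empty (the
    ratio is undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise DataError("IoU undefined: both masks are empty")
    inter = int(np.count_nonzero(a & b))
    return inter / union


def match_detections(
    frame: FrameAnnotation, label: StructureLabel, meta=None
) -> Optional[StructureMask]:
    """Resolve multiple predicted instances of one label to a single mask.

    Highest score wins; ties go to the larger pixel area, then to the first
    occurrence.  Instances without a score rank below any scored instance.
    Returns ``None`` when the frame has no instance of the label.
    """
    candidates = frame.instances(label)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]

    def key(idx_mask):
        idx, m = idx_mask
        score = m.score if m.score is not None else -math.inf
        area = m.area(meta) if meta is not None else int(m.raster.sum()) if m.raster is not None else 0
        return (-score, -area, idx)

    return min(enumerate(candidates), key=key)[1]


@dataclass(frozen=True)
class FrameIoU:
    """IoU of one label in one frame; ``iou`` is None when no prediction matched."""

    frame_index: int
    label: StructureLabel
    iou: Optional[float]
    is_tp: bool

    def __post_init__(self) -> None:
        if self.iou is not None and not (0.0 <= self.iou <= 1.0):
            raise DataError(f"IoU {self.iou} outside [0, 1]")
        if self.iou is None and self.is_tp:
            raise DataError("a frame without a matched prediction cannot be a true positive")


@dataclass
class LabelSummary:
    """Per-label aggregate over the frames that carry ground truth."""

    label: StructureLabel
    n_frames: int
    n_tp: int
    n_fn: int
    recall_percent: float
    iou_mean: float          # missed detections counted as 0
    iou_sd: float
    iou_min: float
    iou_max: float
    iou_mean_detected: Optional[float]  # missed detections excluded
    iou_sd_detected: Optional[float]

    def to_dict(self) -> dict:
        d = {k: (v.value if isinstance(v, StructureLabel) else v) for k, v in self.__dict__.items()}
        return d


@dataclass
class EvaluationReport:
    """Per-frame IoU records plus per-label summaries at one TP threshold."""

    per_frame: list[FrameIoU]
    per_label: dict[StructureLabel, LabelSummary]
    threshold: float = DEFAULT_IOU_THRESHOLD
    n_false_positive: dict[StructureLabel, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "per_label": {lab.value: s.to_dict() for lab, s in self.per_label.items()},
            "n_false_positive": {lab.value: n for lab, n in self.n_false_positive.items()},
        }

    def write_json(self, path: str | Path, extra: Optional[dict] = None) -> None:
        doc = self.to_dict()
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    def write_csv(self, path: str | Path) -> None:
        """Per-frame table with header ``frame,label,iou,is_tp`` (missing iou empty)."""
        lines = ["frame,label,iou,is_tp"]
        for rec in self.per_frame:
            iou_s = "" if rec.iou is None else repr(rec.iou)
            lines.append(f"{rec.frame_index},{rec.label.value},{iou_s},{str(rec.is_tp).lower()}")
        Path(path).write_text("\n".join(lines) + "\n")


def _summary(label: StructureLabel, records: list[FrameIoU]) -> LabelSummary:
    n = len(records)
    n_tp = int(sum(bool(r.is_tp) for r in records))
    with_zero = np.array([r.iou if r.iou is not None else 0.0 for r in records])
    detected = np.array([r.iou for r in records if r.iou is not None])
    sd = float(np.std(with_zero, ddof=1)) if n > 1 else 0.0
    return LabelSummary(
        label=label,
        n_frames=n,
        n_tp=n_tp,
        n_fn=n - n_tp,
        recall_percent=100.0 * n_tp / n,
        iou_mean=float(with_zero.mean()),
        iou_sd=sd,
        iou_min=float(with_zero.min()),
        iou_max=float(with_zero.max()),
        iou_mean_detected=float(detected.mean()) if detected.size else None,
        iou_sd_detected=float(np.std(detected, ddof=1)) if detected.size > 1 else None,
    )


def evaluate(
    gt: AnnotationSet,
    pred: AnnotationSet,
    threshold: float = DEFAULT_IOU_THRESHOLD,
) -> EvaluationReport:
    """Score predictions against ground truth, one IoU per gt frame/label.

    For every frame/label pair that has a ground-truth instance, the matched
    prediction (see :func:`match_detections`) is scored by IoU; a missing
    prediction is a false negative with missing IoU.  Frames without ground
    truth for a label do not enter that label's denominator; predictions on
    such frames are tallied as false positives but excluded from recall.
    """
    if gt.meta.shape != pred.meta.shape:
        raise DataError(f"video geometry mismatch: gt {gt.meta.shape} vs pred {pred.meta.shape}")

    pred_by_index = {f.frame_index: f for f in pred.frames}
    per_frame: list[FrameIoU] = []
    per_label_records: dict[StructureLabel, list[FrameIoU]] = {lab: [] for lab in StructureLabel}
    n_fp: dict[StructureLabel, int] = {lab: 0 for lab in StructureLabel}

    for gframe in gt.frames:
        pframe = pred_by_index.get(gframe.frame_index)
        for label in StructureLabel:
            gt_instances = gframe.instances(label)
            matched = (
                match_detections(pframe, label, pred.meta) if pframe is not None else None
            )
            if not gt_instances:
                if matched is not None:
                    n_fp[label] += 1
                continue
            if matched is None:
                rec = FrameIoU(gframe.frame_index, label, iou=None, is_tp=False)
            else:
                value = iou(gt_instances[0].to_raster(gt.meta), matched.to_raster(pred.meta))
                rec = FrameIoU(gframe.frame_index, label, iou=value, is_tp=value >= threshold)
            per_frame.append(rec)
            per_label_records[label].append(rec)

    per_label = {
        lab: _summary(lab, recs) for lab, recs in per_label_records.items() if recs
    }
    return EvaluationReport(
        per_frame=per_frame,
        per_label=per_label,
        threshold=threshold,
        n_false_positive={lab: n for lab, n in n_fp.items() if n},
    )


@dataclass
class PeakComparison:
    """Group comparison of IoU at elevation-peak frames vs the remaining frames."""

    peak_mean: float
    peak_sd: Optional[float]
    peak_n: int
    lower_mean: float
    lower_sd: Optional[float]
    lower_n: int
    test_name: str
    p_value: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_peak_iou(
    per_frame: Sequence[FrameIoU],
    peak_frames: Iterable[int],
    test: str = "welch",
) -> PeakComparison:
    """Compare per-frame IoU between peak-elevation frames and the rest.

    Segmentation quality of the larynx degrades near the top of its excursion
    (the laryngeal vestibule closes and the contour blends with structures
    above it); this quantifies that drop.  Frames with missing IoU are
    excluded.  ``test`` is ``"welch"`` (two-sided Welch two-sample t) or
    ``"mannwhitney"``; the p-value is omitted when either group has < 2
    values.
    """
    peak_set = set(peak_frames)
    peak = [r.iou for r in per_frame if r.iou is not None and r.frame_index in peak_set]
    lower = [r.iou for r in per_frame if r.iou is not None and r.frame_index not in peak_set]
    if not peak or not lower:
        raise DataError("both the peak and the lower group must be non-empty")

    def mean_sd(vals):
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), (float(arr.std(ddof=1)) if arr.size > 1 else None)

    peak_mean, peak_sd = mean_sd(peak)
    lower_mean, lower_sd = mean_sd(lower)

    p_value: Optional[float] = None
    if len(peak) >= 2 and len(lower) >= 2:
        if test == "welch":
            res = stats.ttest_ind(peak, lower, equal_var=False)
            p_value = float(res.pvalue)
        elif test == "mannwhitney":
            res = stats.mannwhitneyu(peak, lower, alternative="two-sided")
            p_value = float(res.pvalue)
        else:
            raise DataError(f"unknown test {test!r}; use 'welch' or 'mannwhitney'")
        if math.isnan(p_value):  # zero variance in both groups
            p_value = None
    elif test not in ("welch", "mannwhitney"):
        raise DataError(f"unknown test {test!r}; use 'welch' or 'mannwhitney'")

    return PeakComparison(
        peak_mean=peak_mean,
        peak_sd=peak_sd,
        peak_n=len(peak),
        lower_mean=lower_mean,
        lower_sd=lower_sd,
        lower_n=len(lower),
        test_name=test,
        p_value=p_value,
    )


def mask_bce_loss(y: np.ndarray, p: np.ndarray, epsilon: float = 1e-7) -> float:
    """Mean binary cross-entropy of a predicted mask probability map.

    L = -(1/m^2) * sum_ij [ y_ij ln p_ij + (1 - y_ij) ln(1 - p_ij) ]

    ``y`` is the binary target mask, ``p`` the predicted per-pixel foreground
    probability map for the target's class (the caller selects the class
    map).  Probabilities are clamped to ``[epsilon, 1 - epsilon]`` before the
    logarithm.  Natural log; the default mask shape in the detection setting
    is 28 x 28 but any equal shapes are accepted.
    """
    y_arr = np.asarray(y, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if y_arr.shape != p_arr.shape:
        raise DataError(f"mask/probability shape mismatch: {y_arr.shape} vs {p_arr.shape}")
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise DataError("probability map has values outside [0, 1]")
    p_arr = np.clip(p_arr, epsilon, 1.0 - epsilon)
    terms = y_arr * np.log(p_arr) + (1.0 - y_arr) * np.log(1.0 - p_arr)
    return float(-terms.mean())
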