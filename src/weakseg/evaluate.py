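"""Three-pronged evaluation of segmentation quality.

1.  Pixel-level metric suite (accuracy, precision, recall, specificity, IoU,
    boundary-F1) with three aggregations — Global (pooled pixels), Mean
    (unweighted over classes) and Weighted (by class pixel share) — plus raw
    and row-normalised confusion matrices (rows = predicted, columns = actual).
2.  Bounding-box surrogate detection analysis: tight boxes are extracted from
    each mask per 8-connected component, matched one-to-one greedily by IoU
    (threshold 0.1 to discard chance overlap), and summarised as false-positive
    / false-negative ratios and match counts in a low [0.1, 0.5) and a high
    [0.5, 1.0] overlap bin.
3.  Two-sample Kolmogorov–Smirnov comparison of rating-score distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from skimage import measure, segmentation

from .masks import N_CLASSES, CLASS_NAMES, validate_mask

# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics


@dataclass
class ConfusionMatrix:
    """K x K pixel counts; ``counts[i, j]`` = predicted class i, actual class j."""

    counts: np.ndarray
    class_labels: tuple[str, ...] = tuple(CLASS_NAMES.values())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Rows divided by their sums; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.class_labels)


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    idx = pred.ravel().astype(np.int64) * n_classes + truth.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    labels = tuple(CLASS_NAMES.get(c, str(c)) for c in range(n_classes))
    return ConfusionMatrix(counts, labels)


@dataclass
class ClassMetrics:
    """One-vs-rest pixel counts and scores for a single class.

    ``accuracy`` is the per-class segmentation accuracy TP/(TP+FN) — the
    fraction of the class's true pixels that were recovered, i.e. the
    diagonal of the column-normalised confusion matrix.  ``accuracy_as_printed``
    additionally exposes TP/(TP+TN), an alternative formula that circulates in
    some metric tables but is neither standard accuracy nor recall; it is kept
    for transparency only and never aggregated.
    Undefined 0/0 ratios are reported as NaN.
    """

    class_id: int
    tp: int
    fp: int
    fn: int
    tn: int
    bfs: float = math.nan

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def accuracy_as_printed(self) -> float:
        return self._ratio(self.tp, self.tp + self.tn)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def iou(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp + self.fn)

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "accuracy_as_printed": self.accuracy_as_printed,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "iou": self.iou,
            "bfs": self.bfs,
        }


def per_class_metrics(confusion: ConfusionMatrix) -> list[ClassMetrics]:
    """One-vs-rest TP/FP/FN/TN per class from a confusion matrix."""
    counts = confusion.counts
    total = counts.sum()
    out = []
    for c in range(counts.shape[0]):
        tp = int(counts[c, c])
        fp = int(counts[c, :].sum() - tp)  # predicted c, actually something else
        fn = int(counts[:, c].sum() - tp)  # actually c, predicted something else
        tn = int(total - tp - fp - fn)
        out.append(ClassMetrics(class_id=c, tp=tp, fp=fp, fn=fn, tn=tn))
    return out


# ---------------------------------------------------------------------------
# boundary F1


def default_bfs_tolerance(shape: tuple[int, int]) -> int:
    """0.75% of the image diagonal, the usual boundary-matching band."""
    return int(math.ceil(0.0075 * math.hypot(*shape)))


def boundary_f1(
    pred: np.ndarray,
    truth: np.ndarray,
    class_id: int,
    tolerance: int | None = None,
) -> float:
    """Boundary-F1 for one class: harmonic mean of boundary precision/recall.

    A boundary pixel counts as matched when a boundary pixel of the other mask
    lies within ``tolerance`` (Euclidean).  Empty vs empty boundaries -> 1.0;
    empty vs non-empty -> 0.0.
    """
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between pred and truth")
    if tolerance is None:
        tolerance = default_bfs_tolerance(pred.shape)

    b_pred = segmentation.find_boundaries(pred == class_id, mode="inner")
    b_truth = segmentation.find_boundaries(truth == class_id, mode="inner")
    if not b_pred.any() and not b_truth.any():
        return 1.0
    if not b_pred.any() or not b_truth.any():
        return 0.0

    d_truth = ndimage.distance_transform_edt(~b_truth)
    d_pred = ndimage.distance_transform_edt(~b_pred)
    precision = float((d_truth[b_pred] <= tolerance).mean())
    recall = float((d_pred[b_truth] <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class SegMetricsReport:
    """Per-class metrics plus the three aggregations over a set of images."""

    per_class: list[ClassMetrics]
    confusion: ConfusionMatrix
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_bfs: float
    n_images: int

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "global_accuracy": self.global_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "mean_iou": self.mean_iou,
            "weighted_iou": self.weighted_iou,
            "mean_bfs": self.mean_bfs,
            "per_class": [m.to_dict() for m in self.per_class],
            "confusion": self.confusion.counts.tolist(),
            "confusion_row_normalized": self.confusion.row_normalized().tolist(),
        }


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=np.float64)
    if np.isnan(arr).all():
        return math.nan
    return float(np.nanmean(arr))


def aggregate(
    confusions: list[ConfusionMatrix],
    bfs_per_image: list[np.ndarray] | None = None,
    per_image_mean: bool = False,
) -> SegMetricsReport:
    """Pool per-image confusions and aggregate the metric suite.

    Mean scores pool pixels per class across images first, then average over
    classes (NaN classes excluded).  ``per_image_mean=True`` switches to
    averaging per-image per-class scores instead.  Weighted IoU weights each
    class's pooled IoU by its share of actual pixels.
    """
    if not confusions:
        raise ValueError("need at least one image")
    pooled = confusions[0]
    for cm in confusions[1:]:
        pooled = pooled + cm
    metrics = per_class_metrics(pooled)

    total = pooled.n_pixels
    global_accuracy = float(np.trace(pooled.counts)) / total if total else math.nan

    if per_image_mean:
        per_img = [[m for m in per_class_metrics(cm)] for cm in confusions]
        mean_accuracy = _nanmean([m.accuracy for row in per_img for m in row])
        mean_iou = _nanmean([m.iou for row in per_img for m in row])
    else:
        mean_accuracy = _nanmean([m.accuracy for m in metrics])
        mean_iou = _nanmean([m.iou for m in metrics])

    class_pixels = pooled.counts.sum(axis=0).astype(np.float64)  # actual pixels per class
    ious = np.array([m.iou for m in metrics])
    valid = ~np.isnan(ious)
    weighted_iou = (
        float((class_pixels[valid] / total * ious[valid]).sum()) if valid.any() and total else math.nan
    )

    mean_bfs = math.nan
    if bfs_per_image is not None and len(bfs_per_image):
        stacked = np.asarray(bfs_per_image, dtype=np.float64)  # (n_images, K)
        with np.errstate(invalid="ignore"):
            per_class_bfs = np.nanmean(stacked, axis=0)
        for m, b in zip(metrics, per_class_bfs):
            m.bfs = float(b)
        mean_bfs = _nanmean(per_class_bfs)

    return SegMetricsReport(
        per_class=metrics,
        confusion=pooled,
        global_accuracy=global_accuracy,
        mean_accuracy=mean_accuracy,
        mean_iou=mean_iou,
        weighted_iou=weighted_iou,
        mean_bfs=mean_bfs,
        n_images=len(confusions),
    )


def evaluate_segmentation(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    n_classes: int = N_CLASSES,
    bfs_tolerance: int | None = None,
    compute_bfs: bool = True,
) -> SegMetricsReport:
    """Full metric suite for a set of (prediction, truth) mask pairs."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("preds and truths must be equal-length, non-empty lists")
    confusions = [confusion_matrix(p, t, n_classes) for p, t in zip(preds, truths)]
    bfs = None
    if compute_bfs:
        bfs = [
            np.array([boundary_f1(p, t, c, bfs_tolerance) for c in range(n_classes)])
            for p, t in zip(preds, truths)
        ]
    return aggregate(confusions, bfs)


# ---------------------------------------------------------------------------
# bounding boxes


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open [row_min, row_max) x [col_min, col_max)."""

    image_id: str
    class_id: int
    row_min: int
    col_min: int
    row_max: int
    col_max: int
    source: str = "method"

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError("box must have positive extent (half-open bounds)")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)


def extract_bounding_boxes(mask: np.ndarray, image_id: str = "", source: str = "method") -> list[BoundingBox]:
    """Tight box per 8-connected component of each non-background class."""
    mask = validate_mask(mask)
    boxes: list[BoundingBox] = []
    for class_id in range(1, int(mask.max()) + 1 if mask.size else 1):
        labelled = measure.label(mask == class_id, connectivity=2)
        for region in measure.regionprops(labelled):
            rmin, cmin, rmax, cmax = region.bbox
            boxes.append(
                BoundingBox(
                    image_id=image_id,
                    class_id=class_id,
                    row_min=int(rmin),
                    col_min=int(cmin),
                    row_max=int(rmax),
                    col_max=int(cmax),
                    source=source,
                )
            )
    return boxes


def bb_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes' areas."""
    inter_h = min(a.row_max, b.row_max) - max(a.row_min, b.row_min)
    inter_w = min(a.col_max, b.col_max) - max(a.col_min, b.col_min)
    if inter_h <= 0 or inter_w <= 0:
        return 0.0
    inter = inter_h * inter_w
    return inter / (a.area + b.area - inter)


def match_boxes(
    method_boxes: list[BoundingBox],
    reference_boxes: list[BoundingBox],
    tau: float = 0.1,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy one-to-one matching by descending IoU, candidates need IoU >= tau.

    Returns (matches, unmatched_method, unmatched_reference), matches as
    (method_index, reference_index, iou) triples.  The threshold removes
    chance overlap between unrelated events.
    """
    pairs = []
    for i, mb in enumerate(method_boxes):
        for j, rb in enumerate(reference_boxes):
            iou = bb_iou(mb, rb)
            if iou >= tau:
                pairs.append((iou, i, j))
    # stable deterministic order: IoU desc, then indices asc
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_m: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for iou, i, j in pairs:
        if i in used_m or j in used_r:
            continue
        used_m.add(i)
        used_r.add(j)
        matches.append((i, j, iou))
    unmatched_m = [i for i in range(len(method_boxes)) if i not in used_m]
    unmatched_r = [j for j in range(len(reference_boxes)) if j not in used_r]
    return matches, unmatched_m, unmatched_r


DEFAULT_OVERLAP_BINS = ((0.1, 0.49), (0.5, 1.0))


@dataclass
class DetectionReport:
    """Per-class detection agreement between a method's boxes and reference boxes."""

    per_class: dict = field(default_factory=dict)
    total: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "total": self.total}


def _bin_matches(ious: list[float], bins=DEFAULT_OVERLAP_BINS) -> list[int]:
    # printed edges [0.1, 0.49] / [0.5, 1.0] are interpreted as [0.1, 0.5) / [0.5, 1.0]
    counts = [0] * len(bins)
    for iou in ious:
        if iou >= bins[-1][0]:
            counts[-1] += 1
        else:
            counts[0] += 1
    return counts


def detection_report(
    method_boxes: list[BoundingBox],
    reference_boxes: list[BoundingBox],
    tau: float = 0.1,
    bins=DEFAULT_OVERLAP_BINS,
) -> DetectionReport:
    """Match boxes per image and class; summarise FP/FN ratios and overlap bins.

    ``false_positive_ratio`` = unmatched method boxes / total method boxes
    (events the method saw but the reference did not); ``false_negative_ratio``
    = unmatched reference boxes / total reference boxes;
    ``detection_overlap_percent`` = 100 * matched reference boxes / total
    reference boxes.  A zero denominator yields ratio 0 with an ``undefined``
    flag.
    """
    class_ids = sorted({b.class_id for b in method_boxes} | {b.class_id for b in reference_boxes})
    report = DetectionReport()
    tot_m = tot_r = tot_matched = 0
    tot_bins = [0] * len(bins)
    for class_id in class_ids:
        m_cls = [b for b in method_boxes if b.class_id == class_id]
        r_cls = [b for b in reference_boxes if b.class_id == class_id]
        image_ids = sorted({b.image_id for b in m_cls} | {b.image_id for b in r_cls})
        ious: list[float] = []
        n_unmatched_m = n_unmatched_r = 0
        for image_id in image_ids:
            m_img = [b for b in m_cls if b.image_id == image_id]
            r_img = [b for b in r_cls if b.image_id == image_id]
            matches, um, ur = match_boxes(m_img, r_img, tau=tau)
            ious.extend(iou for _, _, iou in matches)
            n_unmatched_m += len(um)
            n_unmatched_r += len(ur)
        n_m, n_r = len(m_cls), len(r_cls)
        n_matched = len(ious)
        bin_counts = _bin_matches(ious, bins)
        entry = {
            "n_method_boxes": n_m,
            "n_reference_boxes": n_r,
            "n_matched": n_matched,
            "false_positive_ratio": (n_unmatched_m / n_m) if n_m else 0.0,
            "false_negative_ratio": (n_unmatched_r / n_r) if n_r else 0.0,
            "fp_ratio_undefined": n_m == 0,
            "fn_ratio_undefined": n_r == 0,
            "overlap_bins": {f"{lo}-{hi}": c for (lo, hi), c in zip(bins, bin_counts)},
            "detection_overlap_percent": (100.0 * n_matched / n_r) if n_r else 0.0,
        }
        report.per_class[class_id] = entry
        tot_m += n_m
        tot_r += n_r
        tot_matched += n_matched
        tot_bins = [a + b for a, b in zip(tot_bins, bin_counts)]
    n_unmatched_m_tot = tot_m - tot_matched
    n_unmatched_r_tot = tot_r - tot_matched
    report.total = {
        "n_method_boxes": tot_m,
        "n_reference_boxes": tot_r,
        "n_matched": tot_matched,
        "false_positive_ratio": (n_unmatched_m_tot / tot_m) if tot_m else 0.0,
        "false_negative_ratio": (n_unmatched_r_tot / tot_r) if tot_r else 0.0,
        "overlap_bins": {f"{lo}-{hi}": c for (lo, hi), c in zip(bins, tot_bins)},
        "detection_overlap_percent": (100.0 * tot_matched / tot_r) if tot_r else 0.0,
    }
    return report


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov rating comparison


def ks_two_sample(scores_a, scores_b) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| and asymptotic p-value."""
    a = np.sort(np.asarray(scores_a, dtype=np.float64))
    b = np.sort(np.asarray(scores_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(special.kolmogorov(en * d))
    return d, min(max(p, 0.0), 1.0)
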