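"""Segmentation evaluation: pixel accuracy, Dice, IoU, average Hausdorff
distance, and ROC AUC.

The first three derive from the per-pixel confusion counts

    ACC = (TP + TN) / (TP + TN + FP + FN)
    DSC = 2 TP / (2 TP + FP + FN)
    IoU = TP / (TP + FP + FN)

and satisfy IoU = DSC / (2 - DSC) whenever the union is non-empty.  The
average Hausdorff distance is the symmetric mean of directed mean
nearest-neighbour distances between the two *boundary* point sets (the
metric is a boundary-error measure; full-mask point sets are available via
``points="mask"``).  AUC uses the rank-statistic (Mann-Whitney) formulation
with half-credit for ties.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import InputError, UndefinedMetricError
from .preprocessing import boundary_pixels

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "dice",
    "iou",
    "average_hausdorff",
    "roc_auc",
    "evaluate_case",
    "aggregate_reports",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class MetricsReport:
    """Per-case metric bundle; ``avgdist`` is in pixels unless a physical
    spacing was supplied, ``auc`` is None when only hard masks are available."""

    acc: float
    dsc: float
    iou: float
    avgdist: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise InputError(f"{name} must contain only {{0,1}}, found values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel TP/TN/FP/FN tally of a predicted mask against ground truth."""
    p = _check_binary(pred, "pred")
    g = _check_binary(gt, "gt")
    if p.shape != g.shape:
        raise InputError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    tn = int(np.count_nonzero(~p & ~g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise InputError("accuracy undefined on zero pixels")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("both masks empty; IoU defined as 1.0", stacklevel=2)
        return 1.0
    return c.tp / denom


def average_hausdorff(
    gt: np.ndarray,
    pred: np.ndarray,
    spacing: tuple[float, float] | None = None,
    points: str = "boundary",
) -> float:
    """Average Hausdorff distance (GtoS/|G| + StoG/|S|) / 2.

    G and S are the boundary point sets of ground truth and prediction
    (mask minus its 4-connected erosion); each directed term is the mean
    Euclidean nearest-neighbour distance, in pixels, or scaled per-axis
    when ``spacing`` (mm per pixel, row/column) is given.  Symmetric in its
    arguments by construction.
    """
    g = _check_binary(gt, "gt")
    s = _check_binary(pred, "pred")
    if g.shape != s.shape:
        raise InputError(f"shape mismatch: gt {g.shape} vs pred {s.shape}")
    if not g.any() or not s.any():
        raise UndefinedMetricError("average Hausdorff undefined for an empty mask")
    if points == "boundary":
        g_pts = np.argwhere(boundary_pixels(g)).astype(np.float64)
        s_pts = np.argwhere(boundary_pixels(s)).astype(np.float64)
    elif points == "mask":
        g_pts = np.argwhere(g).astype(np.float64)
        s_pts = np.argwhere(s).astype(np.float64)
    else:
        raise ValueError(f"points must be 'boundary' or 'mask', got {points!r}")
    if spacing is not None:
        scale = np.asarray(spacing, dtype=np.float64)
        g_pts = g_pts * scale
        s_pts = s_pts * scale
    g_to_s = cKDTree(s_pts).query(g_pts)[0].mean()
    s_to_g = cKDTree(g_pts).query(s_pts)[0].mean()
    return float((g_to_s + s_to_g) / 2.0)


def roc_auc(prob: np.ndarray, gt: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a uniformly drawn positive pixel receives a
    higher score than a uniformly drawn negative one, ties counted half.
    """
    p = np.asarray(prob, dtype=np.float64).ravel()
    g = _check_binary(gt, "gt").ravel()
    if np.any((p < 0) | (p > 1)):
        raise InputError("probabilities must lie in [0,1]")
    n_pos = int(g.sum())
    n_neg = g.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined when ground truth has a single class")
    ranks = rankdata(p)  # average ranks handle ties as half-credit
    return float((ranks[g].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_case(
    prob: np.ndarray,
    gt: np.ndarray,
    threshold: float = 0.5,
    spacing: tuple[float, float] | None = None,
) -> MetricsReport:
    """Binarize a probability map and compute the full metric bundle.

    ``avgdist`` is None (missing) when either mask is empty; ``auc`` is None
    when the ground truth is single-class.
    """
    p = np.asarray(prob, dtype=np.float64)
    g = _check_binary(gt, "gt")
    if p.shape != g.shape:
        raise InputError(f"shape mismatch: prob {p.shape} vs gt {g.shape}")
    pred = (p > threshold).astype(np.uint8)
    c = confusion_counts(pred, g.astype(np.uint8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = MetricsReport(acc=accuracy(c), dsc=dice(c), iou=iou(c), avgdist=None)
    try:
        report.avgdist = average_hausdorff(g.astype(np.uint8), pred, spacing=spacing)
    except UndefinedMetricError:
        report.avgdist = None
    try:
        report.auc = roc_auc(p, g.astype(np.uint8))
    except UndefinedMetricError:
        report.auc = None
    return report


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Unweighted per-image mean of each metric.

    Cases where ``avgdist``/``auc`` is missing are excluded from that
    metric's mean; the number excluded is reported alongside.
    """
    if not reports:
        raise InputError("no reports to aggregate")
    out: dict = {"n_cases": len(reports)}
    for key in ("acc", "dsc", "iou", "avgdist", "auc"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
        missing = len(reports) - len(vals)
        if key in ("avgdist", "auc"):
            out[f"{key}_missing"] = missing
    return out
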