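"""Accuracy, per-class sensitivity, confusion matrices, and the crop-size
sweep.

Accuracy is the fraction of correctly categorized images among all scored
images; sensitivity is the same fraction restricted to one true category.
Multiplet ("discarded") objects are excluded from both by default, as are
edge-rejected detections -- neither enters any numerator or denominator.
Segmentation itself is scored against phantom ground truth by centroid
matching, with a Wilson score interval on the matched fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .labels import (
    BIOLOGICAL_LABELS,
    LABEL_ORDER,
    LABEL_TO_INDEX,
    CellStateLabel,
    as_label,
)
from .phantoms import PhantomGroundTruth
from .segmentation import (
    DetectionRecord,
    DetectionStatus,
    SegmentationParams,
    detect_and_crop,
)

#: Default centroid-matching radius (px) when scoring detections against
#: phantom ground truth: half the default crop radius.
DEFAULT_MATCH_RADIUS = 25.0


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty."""


@dataclass
class ConfusionMatrix:
    """6x6 counts indexed (true label, predicted label) in canonical order."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((6, 6), dtype=np.int64)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (6, 6) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 6x6 nonnegative counts")

    @classmethod
    def from_labels(cls, true_labels, predicted_labels) -> "ConfusionMatrix":
        counts = np.zeros((6, 6), dtype=np.int64)
        for t, p in zip(true_labels, predicted_labels, strict=True):
            counts[LABEL_TO_INDEX[as_label(t)], LABEL_TO_INDEX[as_label(p)]] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, category: CellStateLabel) -> int:
        return int(self.counts[LABEL_TO_INDEX[as_label(category)]].sum())

    def to_frame(self) -> pd.DataFrame:
        names = [l.value for l in LABEL_ORDER]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        names = [l.value for l in LABEL_ORDER]
        return cls(df.loc[names, names].to_numpy())


def compute_accuracy(
    matrix: ConfusionMatrix,
    excluded: set[CellStateLabel] = frozenset({CellStateLabel.DISCARDED}),
) -> float:
    """Trace over the non-excluded submatrix divided by its total."""
    keep = [i for i, l in enumerate(LABEL_ORDER) if l not in excluded]
    sub = matrix.counts[np.ix_(keep, keep)]
    total = sub.sum()
    if total == 0:
        raise UndefinedMetricError("no scored images after exclusions")
    return float(np.trace(sub) / total)


def compute_sensitivity(matrix: ConfusionMatrix, category: CellStateLabel) -> float:
    """Correctly categorized images in the category / images in the category."""
    i = LABEL_TO_INDEX[as_label(category)]
    row = matrix.counts[i]
    if row.sum() == 0:
        raise UndefinedMetricError(f"no images in category {as_label(category).value!r}")
    return float(row[i] / row.sum())


@dataclass
class EvaluationReport:
    accuracy: float
    sensitivity: dict[CellStateLabel, float]
    n_discarded_excluded: int = 0
    n_edge_excluded: int = 0
    sample_loss: float | None = None

    def __post_init__(self):
        vals = [self.accuracy, *self.sensitivity.values()]
        if self.sample_loss is not None:
            vals.append(self.sample_loss)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("all reported fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [("accuracy", self.accuracy)]
        rows += [(f"sensitivity_{k.value}", v) for k, v in self.sensitivity.items()]
        rows += [
            ("n_discarded_excluded", self.n_discarded_excluded),
            ("n_edge_excluded", self.n_edge_excluded),
        ]
        if self.sample_loss is not None:
            rows.append(("sample_loss", self.sample_loss))
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EvaluationReport":
        df = pd.read_csv(path).set_index("metric")["value"]
        sens = {
            l: float(df[f"sensitivity_{l.value}"])
            for l in BIOLOGICAL_LABELS
            if f"sensitivity_{l.value}" in df.index
        }
        return cls(
            accuracy=float(df["accuracy"]),
            sensitivity=sens,
            n_discarded_excluded=int(df.get("n_discarded_excluded", 0)),
            n_edge_excluded=int(df.get("n_edge_excluded", 0)),
            sample_loss=float(df["sample_loss"]) if "sample_loss" in df.index else None,
        )


def report_from_matrix(
    matrix: ConfusionMatrix,
    n_edge_excluded: int = 0,
    sample_loss: float | None = None,
) -> EvaluationReport:
    """Standard report: discarded excluded, sensitivity per biological class."""
    sens = {}
    for label in BIOLOGICAL_LABELS:
        try:
            sens[label] = compute_sensitivity(matrix, label)
        except UndefinedMetricError:
            pass
    return EvaluationReport(
        accuracy=compute_accuracy(matrix),
        sensitivity=sens,
        n_discarded_excluded=matrix.row_sum(CellStateLabel.DISCARDED),
        n_edge_excluded=n_edge_excluded,
        sample_loss=sample_loss,
    )


# ---------------------------------------------------------------------------
# segmentation scoring against phantom ground truth
# ---------------------------------------------------------------------------

def match_detections(
    detections: list[DetectionRecord],
    truth: PhantomGroundTruth,
    radius: float = DEFAULT_MATCH_RADIUS,
    statuses: tuple[DetectionStatus, ...] = (DetectionStatus.KEPT,),
) -> tuple[int, int, int]:
    """Greedy one-to-one centroid matching.

    Returns (n_matched, n_detections_considered, n_true). Detections are
    visited in order of distance to their nearest unmatched true cell.
    """
    considered = [d for d in detections if d.status in statuses]
    true_pts = np.array([c.centroid for c in truth.cells], dtype=float).reshape(-1, 2)
    n_true = len(true_pts)
    if n_true == 0:
        raise UndefinedMetricError("ground truth contains no cells")
    pairs = []
    for di, det in enumerate(considered):
        d = np.hypot(
            true_pts[:, 0] - det.centroid[0], true_pts[:, 1] - det.centroid[1]
        )
        for ti in np.flatnonzero(d <= radius):
            pairs.append((d[ti], di, int(ti)))
    pairs.sort()
    used_d, used_t = set(), set()
    for _, di, ti in pairs:
        if di not in used_d and ti not in used_t:
            used_d.add(di)
            used_t.add(ti)
    return len(used_t), len(considered), n_true


@dataclass
class SegmentationScore:
    recall: float
    precision: float
    n_matched: int
    n_detections: int
    n_true: int
    recall_interval: tuple[float, float]

    @property
    def false_positive_rate(self) -> float:
        """Unmatched kept detections as a fraction of kept detections."""
        if self.n_detections == 0:
            return 0.0
        return 1.0 - self.precision


def segmentation_accuracy(
    detections_per_field: list[list[DetectionRecord]],
    truths: list[PhantomGroundTruth],
    radius: float = DEFAULT_MATCH_RADIUS,
) -> SegmentationScore:
    """Aggregate detection recall/precision over matched field/manifest pairs,
    with a Wilson score interval on the recall."""
    n_matched = n_det = n_true = 0
    for dets, truth in zip(detections_per_field, truths, strict=True):
        m, k, t = match_detections(dets, truth, radius)
        n_matched += m
        n_det += k
        n_true += t
    if n_true == 0:
        raise UndefinedMetricError("no true cells across fields")
    lo, hi = proportion_confint(n_matched, n_true, alpha=0.05, method="wilson")
    return SegmentationScore(
        recall=n_matched / n_true,
        precision=(n_matched / n_det) if n_det else 1.0,
        n_matched=n_matched,
        n_detections=n_det,
        n_true=n_true,
        recall_interval=(float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# crop-size sweep
# ---------------------------------------------------------------------------

def evaluate_crop_size(
    fields,
    truths: list[PhantomGroundTruth],
    crop_sizes: list[int],
    classifier=None,
    params: SegmentationParams = SegmentationParams(),
    radius: float = DEFAULT_MATCH_RADIUS,
) -> pd.DataFrame:
    """Re-run detection + cropping at each crop size; report accuracy and
    sample loss per size.

    sample_loss = (edge_rejected + duplicate_merged + predicted-discarded)
    / total detections. Accuracy is computed over kept crops matched to a
    true cell, comparing the classifier's prediction (crops are rescaled to
    the classifier's input size when they differ) with the true label;
    without a classifier the accuracy column is NaN and loss counts only
    geometric causes. Sizes larger than the field are skipped with a warning.
    """
    from dataclasses import replace as dc_replace

    if len(crop_sizes) < 2:
        raise ValueError("need at least 2 crop sizes to sweep")
    rows = []
    for size in crop_sizes:
        if any(size > min(np.asarray(f).shape) for f in fields):
            warnings.warn(f"crop size {size} exceeds field dimensions: skipped")
            continue
        p = dc_replace(params, crop_size=size)
        n_edge = n_dup = n_pred_discard = n_total = 0
        true_lab, pred_lab = [], []
        for img, truth in zip(fields, truths, strict=True):
            crops, records = detect_and_crop(img, p)
            n_total += len(records)
            n_edge += sum(
                1 for r in records if r.status is DetectionStatus.EDGE_REJECTED
            )
            n_dup += sum(
                1 for r in records if r.status is DetectionStatus.DUPLICATE_MERGED
            )
            if classifier is None:
                continue
            preds = _classify_crops(classifier, [c.pixels for c in crops])
            true_pts = np.array([c.centroid for c in truth.cells]).reshape(-1, 2)
            for crop, pred in zip(crops, preds):
                if pred is CellStateLabel.DISCARDED:
                    n_pred_discard += 1
                d = np.hypot(
                    true_pts[:, 0] - crop.detection.centroid[0],
                    true_pts[:, 1] - crop.detection.centroid[1],
                )
                j = int(d.argmin()) if len(d) else -1
                if j >= 0 and d[j] <= radius:
                    true_lab.append(truth.cells[j].label)
                    pred_lab.append(pred)
        acc = np.nan
        if true_lab:
            try:
                acc = compute_accuracy(ConfusionMatrix.from_labels(true_lab, pred_lab))
            except UndefinedMetricError:
                pass
        loss_frac = (
            (n_edge + n_dup + n_pred_discard) / n_total if n_total else 0.0
        )
        rows.append(
            {
                "crop_size": size,
                "accuracy": acc,
                "sample_loss": loss_frac,
                "n_detections": n_total,
                "n_edge_rejected": n_edge,
                "n_duplicate_merged": n_dup,
                "n_predicted_discarded": n_pred_discard,
            }
        )
    return pd.DataFrame(rows)


def _classify_crops(classifier, crops: list[np.ndarray]) -> list[CellStateLabel]:
    """Predict labels for raw crops, rescaling to the network input if needed."""
    from skimage.transform import resize

    from .model import predict_proba

    if not crops:
        return []
    target = classifier.input_shape[:2]
    batch = []
    for c in crops:
        c = np.asarray(c, dtype=np.float64)
        if c.shape != target:
            c = resize(c, target, order=1, preserve_range=True, anti_aliasing=True)
        batch.append(c)
    probs = predict_proba(classifier, np.stack(batch).astype(np.uint16))
    return [LABEL_ORDER[i] for i in probs.argmax(axis=1)]
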