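"""Quantitative evaluation of segmentations.

Volumetry converts per-label voxel counts into physical volumes (mm^3).
Because cluster labels are arbitrary, predicted labelings are first aligned
to the reference by solving the optimal one-to-one assignment over the
label contingency table; classification quality is then reported one label
versus the rest through the usual confusion-matrix rates (accuracy,
sensitivity, specificity) plus the Dice overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import DimensionError
from .image import OUTSIDE_LABEL

__all__ = [
    "VolumeReport",
    "ConfusionMetrics",
    "label_volumes",
    "match_labels",
    "binary_metrics",
    "overall_accuracy",
]


@dataclass
class VolumeReport:
    """Per-label voxel counts and volumes (mm^3)."""

    counts: dict[int, int]
    volumes_mm3: dict[int, float]
    voxel_volume: float

    def to_dict(self) -> dict:
        return {
            "voxel_volume_mm3": self.voxel_volume,
            "counts": {int(k): int(v) for k, v in self.counts.items()},
            "volumes_mm3": {int(k): float(v)
                            for k, v in self.volumes_mm3.items()},
        }


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    dice: float

    def to_dict(self) -> dict:
        return {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
                for k, v in vars(self).items()}


def _masked_flat(labels, mask):
    labels = np.asarray(labels)
    if mask is not None:
        return labels[np.asarray(mask, dtype=bool)]
    return labels[labels != OUTSIDE_LABEL] if (labels == OUTSIDE_LABEL).any() \
        else labels.ravel()


def label_volumes(labels, voxel_size=(1.0, 1.0, 1.0), mask=None
                  ) -> VolumeReport:
    """Exact per-label voxel counts and volumes = count * voxel volume."""
    flat = _masked_flat(labels, mask)
    vv = float(np.prod(voxel_size))
    uniq, cnt = np.unique(flat, return_counts=True)
    counts = {int(u): int(c) for u, c in zip(uniq, cnt) if u != OUTSIDE_LABEL}
    return VolumeReport(counts,
                        {k: c * vv for k, c in counts.items()}, vv)


def match_labels(pred, truth, mask=None) -> np.ndarray:
    """Permute predicted labels to maximise total overlap with the truth.

    Solves the assignment problem on the label contingency table
    (padded to square when label counts differ); deterministic. Sentinel
    voxels pass through unchanged.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError("prediction and truth must share a shape")
    p = _masked_flat(pred, mask)
    t = _masked_flat(truth, mask)
    np_lab = int(max(p.max(), 0)) + 1
    nt_lab = int(max(t.max(), 0)) + 1
    size = max(np_lab, nt_lab)
    table = np.zeros((size, size), dtype=np.int64)
    np.add.at(table, (p, t), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = np.arange(size)
    mapping[rows] = cols
    out = pred.copy()
    inside = out != OUTSIDE_LABEL
    out[inside] = mapping[out[inside]]
    return out


def binary_metrics(pred, truth, positive_label: int, mask=None
                   ) -> ConfusionMetrics:
    """One-vs-rest confusion counts and rates over masked voxels.

    Expects label-matched inputs. With no positive voxels in the truth the
    sensitivity (and Dice, if the prediction is also empty) is undefined
    and reported as NaN with a warning.
    """
    p = _masked_flat(np.asarray(pred), mask) == positive_label
    t = _masked_flat(np.asarray(truth), mask) == positive_label
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    total = tp + fp + tn + fn
    if tp + fn == 0:
        warnings.warn(f"no voxels of label {positive_label} in the truth; "
                      "sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else float("nan")
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return ConfusionMetrics(tp, fp, tn, fn,
                            accuracy=(tp + tn) / total,
                            sensitivity=sens, specificity=spec, dice=dice)


def overall_accuracy(pred, truth, mask=None) -> float:
    """Fraction of masked voxels whose (matched) label equals the truth."""
    p = _masked_flat(np.asarray(pred), mask)
    t = _masked_flat(np.asarray(truth), mask)
    return float(np.mean(p == t))
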