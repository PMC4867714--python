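"""Pixel-level evaluation of segmentation masks against ground truth.

Confusion counts over the full pixel grid feed the usual ratios — sensitivity,
specificity, accuracy, positive predictive value, false discovery rate — plus
the two spatial-agreement scores (Jaccard overlap and Dice) and a symmetric
boundary Hausdorff distance. Ratios whose denominator is zero are reported as
NaN and listed in ``undefined`` so batch averages can exclude them explicitly
rather than silently counting them as 0 or 1.

The Hausdorff distance is reported both raw in pixels and divided by the
ground-truth mask's equivalent diameter (the diameter of the circle with the
same area), giving a unitless boundary error comparable across image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import directed_hausdorff

from .detect import DetectionResult
from .errors import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "report",
    "evaluate_masks",
    "detection_success",
    "evaluate_batch",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    ppv: float
    fdr: float
    dice: float
    overlap: float
    hausdorff: float      # normalized by the truth mask's equivalent diameter
    hausdorff_px: float   # raw symmetric boundary Hausdorff, pixels
    counts: ConfusionCounts
    #: Names of metrics whose denominator was zero (value reported as NaN).
    undefined: tuple[str, ...] = ()


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a reference mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of the 4-connected inner boundary of ``mask``."""
    structure = ndi.generate_binary_structure(2, 1)
    eroded = ndi.binary_erosion(mask, structure=structure, border_value=1)
    return np.argwhere(mask & ~eroded)


def _hausdorff(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(normalized, pixels) symmetric boundary Hausdorff distance."""
    bp = _boundary(pred)
    bt = _boundary(truth)
    if len(bp) == 0 or len(bt) == 0:
        return float("nan"), float("nan")
    d = max(
        directed_hausdorff(bp, bt)[0],
        directed_hausdorff(bt, bp)[0],
    )
    area = float(np.count_nonzero(truth))
    eq_diameter = 2.0 * np.sqrt(area / np.pi)
    return d / eq_diameter, d


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def report(
    counts: ConfusionCounts,
    pred: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> MetricsReport:
    """Derive all metrics from confusion counts (and masks, for Hausdorff).

    sn = TP/(TP+FN), sp = TN/(TN+FP), acc = (TP+TN)/total, ppv = TP/(TP+FP),
    fdr = FP/(FP+TP), overlap = TP/(TP+FP+FN) (Jaccard), dice =
    2·TP/(2·TP+FP+FN). Hausdorff requires the masks and is NaN (flagged)
    otherwise.
    """
    undefined: list[str] = []
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sn = _ratio(tp, tp + fn, "sn", undefined)
    sp = _ratio(tn, tn + fp, "sp", undefined)
    acc = _ratio(tp + tn, counts.total, "acc", undefined)
    ppv = _ratio(tp, tp + fp, "ppv", undefined)
    fdr = _ratio(fp, fp + tp, "fdr", undefined)
    overlap = _ratio(tp, tp + fp + fn, "overlap", undefined)
    dice = _ratio(2 * tp, 2 * tp + fp + fn, "dice", undefined)
    if pred is not None and truth is not None:
        hd_norm, hd_px = _hausdorff(np.asarray(pred, bool), np.asarray(truth, bool))
        if np.isnan(hd_norm):
            undefined.append("hausdorff")
    else:
        hd_norm, hd_px = float("nan"), float("nan")
        undefined.append("hausdorff")
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, ppv=ppv, fdr=fdr, dice=dice, overlap=overlap,
        hausdorff=hd_norm, hausdorff_px=hd_px, counts=counts,
        undefined=tuple(undefined),
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Convenience: confusion + full report for one mask pair."""
    return report(confusion(pred, truth), pred, truth)


def detection_success(det: DetectionResult, truth: np.ndarray) -> bool:
    """A detection counts as successful iff the detected native center pixel
    lies inside the ground-truth mask (boundary pixels inclusive)."""
    truth = np.asarray(truth, dtype=bool)
    r, c = det.native_center_row, det.native_center_col
    if not (0 <= r < truth.shape[0] and 0 <= c < truth.shape[1]):
        return False
    return bool(truth[r, c])


def evaluate_batch(
    pairs: Iterable[tuple[str, np.ndarray, np.ndarray, DetectionResult | None]],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate ``(name, pred, truth, detection-or-None)`` tuples into a table.

    Columns follow the per-image report; the summary row of means (excluding
    undefined entries) is left to the caller — means over NaN-bearing columns
    should use ``DataFrame.mean(skipna=True)`` deliberately.
    """
    rows = []
    for name, pred, truth, det in pairs:
        rep = evaluate_masks(pred, truth)
        rows.append(
            {
                "image": name,
                "tp": rep.counts.tp, "fp": rep.counts.fp,
                "fn": rep.counts.fn, "tn": rep.counts.tn,
                "sn": rep.sn, "sp": rep.sp, "acc": rep.acc,
                "ppv": rep.ppv, "fdr": rep.fdr,
                "dice": rep.dice, "overlap": rep.overlap,
                "hausdorff_norm": rep.hausdorff, "hausdorff_px": rep.hausdorff_px,
                "detected": detection_success(det, truth) if det is not None else pd.NA,
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
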