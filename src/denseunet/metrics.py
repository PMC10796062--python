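"""Evaluation metrics: Dice, PPV (precision), sensitivity, Hausdorff /
HD95, and IoU, computed per region (WT, TC, ET) from binary masks.

Definitions on confusion counts:
    Dice        = 2TP / (FP + 2TP + FN)
    PPV         = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)
The Hausdorff distance is the max over the two directed distances
max_x min_y ||x - y||; HD95 is the 95th percentile of the pooled directed
point-to-set distances (a literal "0.95 x max" variant is available via
``method="scaled_max"``).  Distances are Euclidean in pixel units on the
2D grid.

Degenerate-mask conventions (flagged in reports): both masks empty ->
overlap metrics 1 and distance 0; exactly one empty -> overlap metrics 0
and the image diagonal as the distance sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import REGIONS, RegionMasks, ValidationError

METRIC_NAMES = ("dice", "ppv", "sensitivity", "hd95", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts for one (prediction, target) mask pair."""

    tp: int
    fp: int
    fn: int


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError(f"{name} mask is not binary (values {uniq[:5]}...)")
        arr = arr.astype(bool)
    return arr


def confusion(pred_mask, target_mask) -> ConfusionCounts:
    """Exact TP/FP/FN pixel counts."""
    pred = _as_binary(pred_mask, "pred")
    target = _as_binary(target_mask, "target")
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & target)),
        fp=int(np.sum(pred & ~target)),
        fn=int(np.sum(~pred & target)),
    )


def dice(c: ConfusionCounts) -> float:
    """2TP / (FP + 2TP + FN); 1.0 when both masks are empty."""
    denom = c.fp + 2 * c.tp + c.fn
    return 2 * c.tp / denom if denom else 1.0


def ppv(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 1.0 when both masks are empty, 0.0 if only pred empty."""
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 1.0 when both masks are empty, 0.0 if only target empty."""
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def iou(pred_mask, target_mask) -> float:
    """|A.B| / |A+B|; 1.0 by convention when both masks are empty."""
    c = confusion(pred_mask, target_mask)
    union = c.tp + c.fp + c.fn
    return c.tp / union if union else 1.0


def _directed_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance from each point of set x to set y."""
    tree = cKDTree(y)
    d, _ = tree.query(x, k=1)
    return np.atleast_1d(d)


def hausdorff(pred_mask, target_mask, percentile: float = 100.0,
              method: str = "percentile") -> float:
    """Hausdorff distance between the positive pixels of two masks.

    ``percentile=100`` gives the classic symmetric maximum of the two
    directed maxima; ``percentile=95`` the robust HD95 (95th percentile of
    the pooled directed distances, linear interpolation).
    ``method="scaled_max"`` instead returns ``(percentile/100) x`` the full
    Hausdorff maximum.  Empty-mask handling: both empty -> 0.0; one empty
    -> the image diagonal as a worst-case sentinel.
    """
    pred = _as_binary(pred_mask, "pred")
    target = _as_binary(target_mask, "target")
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if method not in ("percentile", "scaled_max"):
        raise ValidationError(f"unknown hausdorff method {method!r}")
    px = np.argwhere(pred)
    tx = np.argwhere(target)
    if px.size == 0 and tx.size == 0:
        return 0.0
    if px.size == 0 or tx.size == 0:
        return float(np.linalg.norm(np.asarray(pred.shape, dtype=float)))
    d_pt = _directed_distances(px, tx)
    d_tp = _directed_distances(tx, px)
    if method == "scaled_max":
        return float(max(d_pt.max(), d_tp.max()) * (percentile / 100.0))
    if percentile >= 100.0:
        return float(max(d_pt.max(), d_tp.max()))
    return float(np.percentile(np.concatenate([d_pt, d_tp]), percentile))


def is_degenerate(pred_mask, target_mask) -> bool:
    """True when either mask is empty (metric conventions applied)."""
    return not (np.any(pred_mask) and np.any(target_mask))


@dataclass
class MetricsReport:
    """Per-sample and mean per-region metrics for one prediction set."""

    per_sample: pd.DataFrame  # columns: sample, region, dice, ppv, sensitivity, hd95, iou, flag
    summary: pd.DataFrame     # index: region; columns: METRIC_NAMES

    def to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def summary_dict(self) -> dict:
        return {
            region: {m: float(self.summary.loc[region, m]) for m in METRIC_NAMES}
            for region in self.summary.index
        }


def evaluate_pair(pred: RegionMasks, target: RegionMasks, sample_id=0) -> list[dict]:
    rows = []
    for region in REGIONS:
        pm, tm = pred[region], target[region]
        c = confusion(pm, tm)
        rows.append(
            {
                "sample": sample_id,
                "region": region,
                "dice": dice(c),
                "ppv": ppv(c),
                "sensitivity": sensitivity(c),
                "hd95": hausdorff(pm, tm, percentile=95.0),
                "iou": iou(pm, tm),
                "flag": is_degenerate(pm, tm),
            }
        )
    return rows


def evaluate(predictions: list[RegionMasks], targets: list[RegionMasks],
             sample_ids: list | None = None) -> MetricsReport:
    """Full per-region metric report over aligned prediction/target pairs.

    Means are taken over samples per region; degenerate samples carry a
    ``flag`` so convention-driven values are auditable downstream.
    """
    if len(predictions) != len(targets):
        raise ValidationError(
            f"{len(predictions)} predictions vs {len(targets)} targets"
        )
    if sample_ids is None:
        sample_ids = list(range(len(predictions)))
    rows = []
    for sid, p, t in zip(sample_ids, predictions, targets):
        rows.extend(evaluate_pair(p, t, sample_id=sid))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "region", *METRIC_NAMES, "flag"]
    )
    summary = (
        per_sample.groupby("region")[list(METRIC_NAMES)].mean().reindex(list(REGIONS))
    )
    return MetricsReport(per_sample=per_sample, summary=summary)
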