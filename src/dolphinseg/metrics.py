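"""Segmentation evaluation: confusion counts, overlap scores, Hausdorff, Dice loss.

All scalar scores derive from pixel-level confusion counts.  Percentages
follow the field's printed convention: DSC = 2TP/(FP+2TP+FN) x 100,
JSI = TP/(TP+FN+FP) x 100, accuracy = (TP+TN)/(TP+TN+FP+FN) x 100.  The
empty-against-empty case (tp = fp = fn = 0) is scored 100 for the overlap
metrics: agreement on absence is perfect agreement.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level TP/TN/FP/FN tallies (foreground = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """All scalar scores for one predicted/reference mask pair."""

    dsc_pct: float
    jsi_pct: float
    accuracy_pct: float
    precision_pct: float
    recall_pct: float
    f1_pct: float
    hausdorff_px: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not set(values.tolist()) <= {0, 1}:
        raise ValueError(f"{name} must be binary {{0,1}}; found values {values.tolist()}")
    return mask.astype(bool)


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between two binary masks of identical shape."""
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = _check_binary(pred, "pred_mask")
    t = _check_binary(truth, "truth_mask")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient as a percentage, 2TP/(FP+2TP+FN) x 100."""
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        return 100.0
    return 2.0 * c.tp / denom * 100.0


def jsi(c: ConfusionCounts) -> float:
    """Jaccard similarity index (intersection over union) as a percentage."""
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        return 100.0
    return c.tp / denom * 100.0


def accuracy(c: ConfusionCounts) -> float:
    """Pixel accuracy (TP+TN)/(all pixels) as a percentage."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero compared pixels")
    return (c.tp + c.tn) / c.total * 100.0


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1, each as a percentage.

    When tp = fp = fn = 0 every quantity is 100 (empty agreement); otherwise a
    zero denominator for precision or recall scores that metric 0.
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 100.0, 100.0, 100.0
    precision = c.tp / (c.tp + c.fp) * 100.0 if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) * 100.0 if c.tp + c.fn else 0.0
    if precision + recall == 0.0:
        return precision, recall, 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def hausdorff(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Symmetric Hausdorff distance (pixels) between foreground point sets.

    Uses exact Euclidean distances over the full foreground regions (not
    boundaries).  If either mask has no foreground the distance is undefined
    and ``inf`` is returned with a warning.
    """
    pred = _check_binary(np.asarray(pred_mask), "pred_mask")
    truth = _check_binary(np.asarray(truth_mask), "truth_mask")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    pts_p = np.argwhere(pred)
    pts_t = np.argwhere(truth)
    if len(pts_p) == 0 or len(pts_t) == 0:
        warnings.warn("empty foreground: Hausdorff distance undefined, returning inf")
        return math.inf
    d_pt = directed_hausdorff(pts_p, pts_t)[0]
    d_tp = directed_hausdorff(pts_t, pts_p)[0]
    return float(max(d_pt, d_tp))


def dice_loss(pred_prob: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2*sum(Y*P) + eps) / (sum(Y) + sum(P) + eps).

    ``pred_prob`` holds probabilities in [0,1]; ``truth`` is a binary mask.
    ``eps`` stabilises the empty-mask case (default 1.0).
    """
    p = np.asarray(pred_prob, dtype=float)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("pred_prob values must lie in [0, 1]")
    tb = _check_binary(t, "truth").astype(float)
    inter = float((p * tb).sum())
    denom = float(tb.sum() + p.sum()) + eps
    return 1.0 - (2.0 * inter + eps) / denom


def evaluate_pair(pred_mask: np.ndarray, truth_mask: np.ndarray) -> MetricReport:
    """Compute the full scalar report for one predicted/reference pair."""
    c = confusion_counts(pred_mask, truth_mask)
    p, r, f1 = precision_recall_f1(c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hd = hausdorff(pred_mask, truth_mask)
    return MetricReport(
        dsc_pct=dsc(c),
        jsi_pct=jsi(c),
        accuracy_pct=accuracy(c),
        precision_pct=p,
        recall_pct=r,
        f1_pct=f1,
        hausdorff_px=hd,
    )


METRIC_COLUMNS = ["dsc", "jsi", "accuracy", "precision", "recall", "f1", "hausdorff"]


def evaluate_table(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Per-image metric table for (id, pred_mask, truth_mask) triples."""
    rows = []
    for sample_id, pred, truth in pairs:
        rep = evaluate_pair(pred, truth)
        rows.append(
            {
                "id": sample_id,
                "dsc": rep.dsc_pct,
                "jsi": rep.jsi_pct,
                "accuracy": rep.accuracy_pct,
                "precision": rep.precision_pct,
                "recall": rep.recall_pct,
                "f1": rep.f1_pct,
                "hausdorff": rep.hausdorff_px,
            }
        )
    return pd.DataFrame(rows, columns=["id"] + METRIC_COLUMNS)


def summarize_table(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean and standard deviation (population) per metric column."""
    summary: dict[str, dict[str, float]] = {}
    for col in METRIC_COLUMNS:
        vals = table[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        summary[col] = {
            "mean": float(finite.mean()) if len(finite) else math.inf,
            "sd": float(finite.std()) if len(finite) else math.inf,
            "n": int(len(vals)),
        }
    return summary


def write_metric_outputs(table: pd.DataFrame, csv_path: Path | str, json_path: Path | str) -> None:
    """Write the per-image CSV (2-decimal percentages) and the JSON summary."""
    rounded = table.copy()
    for col in METRIC_COLUMNS:
        rounded[col] = rounded[col].map(lambda v: round(v, 2) if math.isfinite(v) else v)
    rounded.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(summarize_table(table), fh, indent=2, sort_keys=True)
        fh.write("\n")
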