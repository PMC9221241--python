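"""Pixel-level evaluation and lesion-size stratification.

Metrics are computed per slice from the binary confusion counts:
DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), recall = TP/(TP+FN),
precision = TP/(TP+FP); mIoU is the mean of the foreground and background
IoU of the slice. Degenerate denominators (empty ground truth and empty
prediction) return 1.0 by convention.

Slices are stratified by ground-truth foreground pixel count with half-open
intervals: lesion-free (0), small [1, 100), medium [100, 1000),
large [1000, inf). Reports aggregate per-slice metrics macro-averaged
within each stratum; lesion-free slices are counted but excluded from the
metric rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

LESION_FREE = "lesion_free"
SMALL = "small"
MEDIUM = "medium"
LARGE = "large"
STRATA = (SMALL, MEDIUM, LARGE)

SMALL_MAX = 100
MEDIUM_MAX = 1000


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_pair(gt, pred):
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise InputError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    return gt.astype(bool), pred.astype(bool)


def confusion_counts(gt, pred) -> ConfusionCounts:
    g, p = _check_pair(gt, pred)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = int(np.count_nonzero(~g & ~p))
    return ConfusionCounts(tp, fp, fn, tn)


def _safe(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dsc(gt, pred) -> float:
    c = confusion_counts(gt, pred)
    return _safe(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def iou(gt, pred) -> float:
    c = confusion_counts(gt, pred)
    return _safe(float(c.tp), float(c.tp + c.fp + c.fn))


def recall(gt, pred) -> float:
    c = confusion_counts(gt, pred)
    return _safe(float(c.tp), float(c.tp + c.fn))


def precision(gt, pred) -> float:
    c = confusion_counts(gt, pred)
    return _safe(float(c.tp), float(c.tp + c.fp))


def miou(gt, pred) -> float:
    """Mean of foreground IoU and background IoU for one slice."""
    c = confusion_counts(gt, pred)
    fg = _safe(float(c.tp), float(c.tp + c.fp + c.fn))
    bg = _safe(float(c.tn), float(c.tn + c.fp + c.fn))
    return 0.5 * (fg + bg)


def stratify_by_lesion_size(gt) -> str:
    """Stratum label from the ground-truth foreground pixel count."""
    c = int(np.count_nonzero(np.asarray(gt)))
    if c == 0:
        return LESION_FREE
    if c < SMALL_MAX:
        return SMALL
    if c < MEDIUM_MAX:
        return MEDIUM
    return LARGE


_METRICS = {"dsc": dsc, "miou": miou, "recall": recall, "precision": precision}


@dataclass
class MetricsReport:
    """Per-stratum and overall macro-averaged metrics.

    ``rows`` maps stratum name (and "overall") to a dict with keys
    n_slices/dsc/miou/recall/precision. Strata with no slices are absent.
    ``n_lesion_free`` counts excluded lesion-free slices.
    """

    rows: dict
    n_lesion_free: int

    def to_frame(self) -> pd.DataFrame:
        order = [s for s in (*STRATA, "overall") if s in self.rows]
        df = pd.DataFrame.from_dict(self.rows, orient="index").loc[order]
        df.index.name = "stratum"
        return df.reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __getitem__(self, stratum: str) -> dict:
        return self.rows[stratum]


def report_from_pairs(pairs) -> MetricsReport:
    """Build a report from (gt, pred) mask pairs."""
    per_stratum: dict[str, list[dict]] = {s: [] for s in STRATA}
    n_free = 0
    for gt, pred in pairs:
        stratum = stratify_by_lesion_size(gt)
        if stratum == LESION_FREE:
            n_free += 1
            continue
        per_stratum[stratum].append({k: f(gt, pred) for k, f in _METRICS.items()})
    rows = {}
    everything = []
    for s in STRATA:
        vals = per_stratum[s]
        if not vals:
            continue
        everything.extend(vals)
        rows[s] = {"n_slices": len(vals)}
        rows[s].update({k: float(np.mean([v[k] for v in vals])) for k in _METRICS})
    if everything:
        rows["overall"] = {"n_slices": len(everything)}
        rows["overall"].update(
            {k: float(np.mean([v[k] for v in everything])) for k in _METRICS}
        )
    return MetricsReport(rows=rows, n_lesion_free=n_free)


def evaluate(net, records) -> MetricsReport:
    """Evaluate a predictor over SliceRecords; deterministic given both.

    ``net`` is anything exposing ``predict_mask(image) -> binary mask``
    (a FECCNet, a fitted estimator's network, or a stub in tests).
    """
    pairs = ((rec.mask, net.predict_mask(rec.image)) for rec in records)
    return report_from_pairs(pairs)
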