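"""Pixelwise segmentation metrics: confusion counts, derived rates, ROC.

Stack metrics are micro-averaged: counts are pooled over all slices before
deriving rates, matching how one value is reported per test-image stack.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn import metrics as _skm

from .types import BinaryMask, MetricsReport, as_slices

__all__ = ["confusion", "metrics", "stack_metrics", "roc_curve", "roc_auc",
           "metrics_from_pr", "export_report"]


def _mask_arr(m) -> np.ndarray:
    a = np.asarray(m.values if isinstance(m, BinaryMask) else m)
    return a != 0


def confusion(seg, truth):
    """Pixelwise (TP, FP, TN, FN) between a segmentation and ground truth."""
    s = _mask_arr(seg)
    t = _mask_arr(truth)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: seg {s.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(s & t))
    fp = int(np.count_nonzero(s & ~t))
    fn = int(np.count_nonzero(~s & t))
    tn = s.size - tp - fp - fn
    return tp, fp, tn, fn


def metrics(TP, FP, TN, FN) -> MetricsReport:
    """Derive TPR, FPR, precision, accuracy, F-value and Jaccard from counts."""
    return MetricsReport(TP=TP, FP=FP, TN=TN, FN=FN)


def stack_metrics(segs, truths) -> MetricsReport:
    """Micro-averaged metrics: confusion counts pooled across all slices."""
    s = as_slices(segs)
    t = as_slices(truths)
    tp, fp, tn, fn = confusion(s, t)
    return metrics(tp, fp, tn, fn)


def metrics_from_pr(precision: float, recall: float):
    """(F, Jaccard) from precision P and recall R.

    F = 2PR/(P+R) and, via J = F/(2-F), J = PR/(P+R-PR).
    """
    if precision + recall == 0:
        raise ValueError("precision + recall must be positive")
    f = 2 * precision * recall / (precision + recall)
    j = precision * recall / (precision + recall - precision * recall)
    return f, j


def roc_curve(maps, truths):
    """ROC points (FPR, TPR) over pooled pixels, one per distinct threshold.

    The curve includes the (0, 0) and (1, 1) endpoints and is monotone
    non-decreasing in both coordinates as the threshold decreases.
    """
    scores = np.asarray(maps.values if hasattr(maps, "values") else maps,
                        dtype=np.float64).ravel()
    y = _mask_arr(truths).ravel().astype(np.int8)
    if y.min() == y.max():
        raise ValueError("ground truth must contain both classes")
    fpr, tpr, thr = _skm.roc_curve(y, scores, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(maps, truths) -> float:
    pts = roc_curve(maps, truths)
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


def export_report(report: MetricsReport, path, fmt: str | None = None):
    """Write a metrics report to CSV or JSON (inferred from the suffix)."""
    from pathlib import Path
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    d = report.as_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        keys = list(d)
        path.write_text(",".join(keys) + "\n"
                        + ",".join(str(d[k]) for k in keys) + "\n")
    return path
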