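"""Binary evaluation with the long-non-coding class as positive.

Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/total as a percentage, and
Matthews' correlation coefficient; TP counts correctly identified lncRNAs,
TN correctly identified mRNAs.  AUC is computed from non-coding scores by the
rank (Mann-Whitney) statistic with midranks for ties; shortcut calls carry a
degenerate score of 1.0 and are excluded from ROC analysis by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .sequence_io import NONCODING


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    """Sn/Sp as fractions, ACC as a percentage, MCC in [-1, 1]."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None


def confusion(y_true, y_pred, positive_label: str = NONCODING) -> ConfusionCounts:
    """Count the four outcome categories with lncRNA (NONCODING) positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    tp = int(np.sum((y_true == positive_label) & (y_pred == positive_label)))
    fn = int(np.sum((y_true == positive_label) & (y_pred != positive_label)))
    tn = int(np.sum((y_true != positive_label) & (y_pred != positive_label)))
    fp = int(np.sum((y_true != positive_label) & (y_pred == positive_label)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sn, Sp, ACC (%), MCC from a confusion matrix.

    A zero denominator yields 0 for the affected quantity (standard MCC
    convention for degenerate matrices; Sn/Sp are 0 when their class is
    absent).
    """
    if c.total <= 0:
        raise ValidationError("empty confusion matrix")
    sn = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0
    acc = (c.TP + c.TN) / c.total * 100.0
    denom = (
        (c.TP + c.FP) * (c.TN + c.FN) * (c.TP + c.FN) * (c.TN + c.FP)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom else 0.0
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(scores, y_true, positive_label: str = NONCODING) -> float:
    """AUC by the Mann-Whitney rank statistic with tie midranks."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValidationError("scores and labels differ in length")
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(scores, y_true, positive_label: str = NONCODING) -> np.ndarray:
    """Empirical ROC curve as an (n, 2) array of (FPR, TPR) points."""
    from sklearn.metrics import roc_curve as _sk_roc_curve

    y = (np.asarray(y_true) == positive_label).astype(int)
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def write_roc_points(points: np.ndarray, path) -> None:
    np.savetxt(path, points, delimiter="\t", header="fpr\ttpr", comments="")


def format_metrics(c: ConfusionCounts, m: MetricSet) -> str:
    """Pretty-printed metrics block echoing the confusion counts."""
    lines = [
        "confusion  TP=%d FN=%d TN=%d FP=%d" % (c.TP, c.FN, c.TN, c.FP),
        f"Sn   {m.sn:.4f}",
        f"Sp   {m.sp:.4f}",
        f"ACC  {m.acc:.2f}%",
        f"MCC  {m.mcc:.4f}",
    ]
    if m.auc is not None:
        lines.append(f"AUC  {m.auc:.4f}")
    return "\n".join(lines)


def write_metrics(c: ConfusionCounts, m: MetricSet, path) -> None:
    """TSV metrics report including the raw confusion counts."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, val in (
            ("TP", c.TP), ("FN", c.FN), ("TN", c.TN), ("FP", c.FP),
            ("Sn", f"{m.sn:.6g}"), ("Sp", f"{m.sp:.6g}"),
            ("ACC_percent", f"{m.acc:.6g}"), ("MCC", f"{m.mcc:.6g}"),
        ):
            fh.write(f"{name}\t{val}\n")
        if m.auc is not None:
            fh.write(f"AUC\t{m.auc:.6g}\n")


def plot_roc(scores, y_true, ax=None, positive_label: str = NONCODING):
    """Plot the ROC curve; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    pts = roc_curve_points(scores, y_true, positive_label)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pts[:, 0], pts[:, 1])
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"ROC (AUC = {roc_auc(scores, y_true, positive_label):.4f})")
    return ax
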