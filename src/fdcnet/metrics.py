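"""Classification and image-fidelity metrics.

Accuracy and sensitivity are reported in percent from confusion counts
(one-vs-rest per class for multiclass, macro-averaged).  Image metrics
use the standard reference-first definitions: MSE is the mean squared
difference, PSNR = 10 log10(max^2 / MSE) and SNR = 10 log10(sum a^2 /
sum (a-b)^2), both capped at a documented ceiling when the error is
exactly zero.  ROC curves are computed over all score thresholds and
the AUC by the trapezoid rule, which coincides with the rank statistic
P(score+ > score-) + 1/2 P(tie).

Note SNR is *not* symmetric in its arguments (the first is the
reference signal), while MSE is; both facts are covered by tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "accuracy",
    "sensitivity",
    "multiclass_accuracy",
    "macro_sensitivity",
    "mse",
    "psnr",
    "snr",
    "roc_auc",
    "roc_auc_multiclass",
    "DB_CAP",
]

#: Decibel value reported instead of infinity when the error is zero.
DB_CAP = 99.0


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
                   tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)))


def accuracy(counts: ConfusionCounts) -> float:
    """100 * (tp + tn) / total."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for zero samples")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    """100 * tp / (tp + fn); undefined when no positives exist."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def multiclass_accuracy(y_true, y_pred) -> float:
    """Percent of exact label matches."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("accuracy undefined for zero samples")
    return 100.0 * float(np.mean(y_true == y_pred))


def macro_sensitivity(y_true, y_pred) -> float:
    """Macro one-vs-rest average of per-class sensitivity, in percent."""
    vals = [sensitivity(ConfusionCounts.from_labels(y_true, y_pred, c))
            for c in np.unique(y_true)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Image fidelity
# ---------------------------------------------------------------------------

def _pair(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared difference (symmetric)."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, max_value: float = 255.0) -> float:
    """10 log10(max^2 / MSE) in dB; DB_CAP when the images are identical."""
    m = mse(a, b)
    if m == 0:
        return DB_CAP
    return min(float(10.0 * np.log10(max_value * max_value / m)), DB_CAP)


def snr(a, b) -> float:
    """10 log10(sum a^2 / sum (a-b)^2) dB, with ``a`` the reference."""
    a, b = _pair(a, b)
    noise = float(np.sum((a - b) ** 2))
    if noise == 0:
        return DB_CAP
    sig = float(np.sum(a * a))
    if sig == 0:
        return -DB_CAP
    return min(float(10.0 * np.log10(sig / noise)), DB_CAP)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive=1):
    """ROC curve over all thresholds and trapezoid AUC.

    Returns ``((thresholds, fpr, tpr), auc)``.  Requires both classes
    present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == positive
    if pos.all() or not pos.any():
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (thr, fpr, tpr), auc


def roc_auc_multiclass(scores, labels, classes: Optional[Sequence] = None) -> float:
    """Macro one-vs-rest AUC for per-class score columns (n, K)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    aucs = []
    for k, c in enumerate(classes):
        y = labels == c
        if y.all() or not y.any():
            continue
        _, auc = roc_auc(scores[:, k], y.astype(int), positive=1)
        aucs.append(auc)
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


@dataclass
class MetricsReport:
    """The six headline evaluation fields."""

    accuracy: float      # percent
    sensitivity: float   # percent
    mse: float
    psnr: float          # dB
    snr: float           # dB
    auc: float

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must be a percentage")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def roc_to_csv(curve, path) -> None:
    """Write (threshold, fpr, tpr) rows as CSV."""
    thr, fpr, tpr = curve
    with open(path, "w") as fh:
        fh.write("threshold,fpr,tpr\n")
        for row in zip(thr, fpr, tpr):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
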