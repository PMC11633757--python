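"""Per-class diagnostic metrics with equal-weight macro averaging.

For each tissue class, prediction quality is summarised one-vs-rest from
the confusion matrix as

    specificity  S  = TN / (TN + FP)
    sensitivity  R  = TP / (TP + FN)
    precision    P  = TP / (TP + FP)
    F1           F1 = 2 P R / (P + R)

and macro values are unweighted arithmetic means over classes, giving each
class equal importance regardless of its pixel prevalence.  Classes with a
zero denominator are reported as undefined (NaN) and excluded from the
macro average with a warning.  Report tables round half-up to 2 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .images import AnnotationMask
from .taxonomy import get_taxonomy

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "metrics",
    "macro_average",
    "f1_score",
    "round_half_up",
    "report_table",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed report tables."""
    if not np.isfinite(x):
        return x
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """n x n integer count table; rows are truth, columns prediction."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match class_names")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index k."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn


@dataclass
class ClassMetrics:
    """Per-class S, R, P, F1 plus their macro (unweighted mean) values."""

    class_names: tuple[str, ...]
    specificity: np.ndarray
    sensitivity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    macro_specificity: float
    macro_sensitivity: float
    macro_precision: float
    macro_f1: float


def confusion(pred: AnnotationMask, truth: AnnotationMask) -> ConfusionMatrix:
    """Pixelwise confusion matrix between prediction and ground truth."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.level != truth.level:
        raise ValueError(f"taxonomy level mismatch: {pred.level} vs {truth.level}")
    if pred.labels.size == 0:
        raise ValueError("empty masks")
    tax = get_taxonomy(pred.level) if pred.level in (15, 6, 3) else None
    names = tax.names if tax else tuple(str(i) for i in range(int(truth.labels.max()) + 1))
    labels = np.arange(len(names))
    counts = _sk_confusion(truth.labels.ravel(), pred.labels.ravel(), labels=labels)
    return ConfusionMatrix(counts=counts, class_names=tuple(names))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN when P + R = 0."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class one-vs-rest S, R, P, F1 and their macro averages."""
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    n = len(cm.class_names)
    S = np.full(n, np.nan)
    R = np.full(n, np.nan)
    P = np.full(n, np.nan)
    F = np.full(n, np.nan)
    for k in range(n):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        if tn + fp > 0:
            S[k] = tn / (tn + fp)
        if tp + fn > 0:
            R[k] = tp / (tp + fn)
        if tp + fp > 0:
            P[k] = tp / (tp + fp)
        if np.isfinite(P[k]) and np.isfinite(R[k]):
            F[k] = f1_score(P[k], R[k])
    for arr, label in ((S, "specificity"), (R, "sensitivity"), (P, "precision"), (F, "F1")):
        if np.isnan(arr).any():
            bad = [cm.class_names[i] for i in np.flatnonzero(np.isnan(arr))]
            warnings.warn(
                f"{label} undefined for class(es) {bad}; excluded from macro average",
                stacklevel=2,
            )
    return ClassMetrics(
        class_names=cm.class_names,
        specificity=S,
        sensitivity=R,
        precision=P,
        f1=F,
        macro_specificity=macro_average(S),
        macro_sensitivity=macro_average(R),
        macro_precision=macro_average(P),
        macro_f1=macro_average(F),
    )


def macro_average(values) -> float:
    """Unweighted arithmetic mean over defined (non-NaN) per-class values."""
    values = np.asarray(values, dtype=float)
    defined = values[np.isfinite(values)]
    if defined.size == 0:
        raise ValueError("macro average needs at least one defined value")
    return float(defined.mean())


def report_table(cm: ConfusionMatrix, decimals: int = 2) -> pd.DataFrame:
    """Table of per-class metrics plus the Average row, rounded half-up."""
    m = metrics(cm)
    rows = []
    for i, name in enumerate(m.class_names):
        rows.append(
            {
                "Class": name,
                "Specificity": round_half_up(m.specificity[i], decimals),
                "Sensitivity": round_half_up(m.sensitivity[i], decimals),
                "Precision": round_half_up(m.precision[i], decimals),
                "F1 score": round_half_up(m.f1[i], decimals),
            }
        )
    rows.append(
        {
            "Class": "Average",
            "Specificity": round_half_up(m.macro_specificity, decimals),
            "Sensitivity": round_half_up(m.macro_sensitivity, decimals),
            "Precision": round_half_up(m.macro_precision, decimals),
            "F1 score": round_half_up(m.macro_f1, decimals),
        }
    )
    return pd.DataFrame(rows)


def plot_confusion(cm: ConfusionMatrix, path=None):
    """Confusion-matrix heatmap (row-normalized); saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = cm.counts / np.maximum(cm.counts.sum(axis=1, keepdims=True), 1)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(norm, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cm.class_names)), cm.class_names, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.class_names)), cm.class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
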