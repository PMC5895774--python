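"""ROC curves, AUC, sensitivity/specificity and confusion summaries.

AUC is the trapezoidal area under the empirical ROC over all distinct
score thresholds, equivalently the Mann-Whitney U statistic divided by
``n_pos * n_neg`` (tied score pairs contribute 0.5). The curve and area
are computed with scikit-learn; missing scores are excluded and counted,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["RocCurve", "ConfusionSummary", "roc_auc", "confusion"]


@dataclass
class RocCurve:
    """Empirical ROC operating points and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int
    n_excluded: int = 0

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})

    def plot(self, ax=None):
        """Cosmetic ROC plot; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {self.auc:.4f}")
        return ax


def roc_auc(scores, labels, positive, direction: str = "high") -> RocCurve:
    """ROC curve and AUC of a score against a binary labeling.

    ``direction="high"`` means higher scores indicate the positive
    class; ``"low"`` flips the score. Missing (NaN) scores are dropped
    and counted in ``n_excluded``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels have different lengths")
    keep = ~np.isnan(scores)
    n_excluded = int((~keep).sum())
    scores, labels = scores[keep], labels[keep]
    y = (labels == positive).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    s = scores if direction == "high" else -scores
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return RocCurve(fpr, tpr, thr, auc, direction, n_pos, n_neg, n_excluded)


@dataclass
class ConfusionSummary:
    """Predicted-vs-true counts with sensitivity/specificity.

    Sensitivity is TP / (TP + FN) over the designated positive class;
    specificity is TN / (TN + FP) over all non-positive subjects, where
    any prediction other than the positive label counts as negative.
    Exact fractions are retained; percent fields are rounded for
    display.
    """

    table: pd.DataFrame
    positive: str
    sensitivity: float
    specificity: float
    n: int

    @property
    def sensitivity_pct(self) -> int:
        return round(self.sensitivity * 100)

    @property
    def specificity_pct(self) -> int:
        return round(self.specificity * 100)


def confusion(pred, true, positive) -> ConfusionSummary:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true):
        raise ValueError("pred and true have different lengths")
    table = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(pred, name="predicted"), dropna=False
    )
    pos_true = true == positive
    pos_pred = pred == positive
    tp = int((pos_true & pos_pred).sum())
    fn = int((pos_true & ~pos_pred).sum())
    tn = int((~pos_true & ~pos_pred).sum())
    fp = int((~pos_true & pos_pred).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionSummary(table, positive, sens, spec, n=len(pred))
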