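"""Single-marker threshold baselines.

Diagnostic cutoffs are set at a 95% confidence limit of the geometric
mean of the positive (PCa) group's marker values: the *lower* limit for
PSA (high PSA indicates cancer) and the *upper* limit for DHEAS (low
DHEAS indicates cancer). The confidence interval is a Student-t interval
on the natural logs:

    gm = exp(mean(ln x)),   CI = exp(mean(ln x) -/+ t_{1-a/2, n-1} * sd(ln x) / sqrt(n))

On the embedded clinical table these evaluate to 7.385 ng/mL for PSA
(19 non-missing PCa values) and 888.7 ng/mL for DHEAS (20 PCa values).

The boundary convention assigns values exactly at the threshold to the
"high" side: PSA >= threshold -> PCa; DHEAS >= threshold -> BPH/HC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GmCiResult",
    "geometric_mean_ci",
    "psa_classify",
    "dheas_classify",
    "GeometricMeanThresholdClassifier",
    "NON_POSITIVE_LABEL",
    "UNCLASSIFIED",
]

NON_POSITIVE_LABEL = "BPH/HC"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GmCiResult:
    """Geometric mean with its confidence limits (ng/mL)."""

    gm: float
    lo: float
    hi: float
    n: int
    level: float


def geometric_mean_ci(values, level: float = 0.95) -> GmCiResult:
    """Geometric mean and t-based CI of strictly positive values."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    if np.any(~(x > 0)):
        raise ValueError("geometric mean requires strictly positive values")
    logs = np.log(x)
    n = len(logs)
    m = logs.mean()
    se = logs.std(ddof=1) / np.sqrt(n)
    t = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return GmCiResult(
        gm=float(np.exp(m)),
        lo=float(np.exp(m - t * se)),
        hi=float(np.exp(m + t * se)),
        n=n,
        level=level,
    )


def psa_classify(psa: float | None, threshold: float) -> str:
    """PSA >= threshold -> PCa; below -> BPH/HC; missing -> unclassified."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if psa is None or (isinstance(psa, float) and np.isnan(psa)):
        return UNCLASSIFIED
    return "PCa" if psa >= threshold else NON_POSITIVE_LABEL


def dheas_classify(dheas: float, threshold: float) -> str:
    """DHEAS below threshold -> PCa; at or above -> BPH/HC."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if dheas is None or (isinstance(dheas, float) and np.isnan(dheas)):
        raise ValueError("DHEAS value is required")
    return "PCa" if dheas < threshold else NON_POSITIVE_LABEL


class GeometricMeanThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-marker cutoff classifier with a geometric-mean-CI threshold.

    Parameters
    ----------
    positive_class : label whose marker distribution sets the threshold.
    side : {"lower", "upper"}
        Which CI limit of the positive group becomes the cutoff
        ("lower" for PSA, "upper" for DHEAS).
    direction : {"high", "low"}
        Whether high ("high", PSA) or low ("low", DHEAS) marker values
        indicate the positive class. Boundary values go to the high side.
    level : confidence level of the interval (default 0.95).

    ``fit(X, y)`` takes a single marker column; missing (NaN) positives
    are excluded from threshold estimation. ``predict`` returns the
    positive label, "BPH/HC", or "unclassified" for missing values.
    """

    def __init__(self, positive_class="PCa", side="lower", direction="high", level=0.95):
        self.positive_class = positive_class
        self.side = side
        self.direction = direction
        self.level = level

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if len(x) != len(y):
            raise ValueError("X and y have different lengths")
        pos = x[(y == self.positive_class) & ~np.isnan(x)]
        self.ci_ = geometric_mean_ci(pos, level=self.level)
        self.threshold_ = self.ci_.lo if self.side == "lower" else self.ci_.hi
        self.classes_ = np.array([self.positive_class, NON_POSITIVE_LABEL])
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        x = np.asarray(X, dtype=float).reshape(-1)
        out = np.empty(len(x), dtype=object)
        for j, v in enumerate(x):
            if np.isnan(v):
                out[j] = UNCLASSIFIED
            elif self.direction == "high":
                out[j] = self.positive_class if v >= self.threshold_ else NON_POSITIVE_LABEL
            else:
                out[j] = self.positive_class if v < self.threshold_ else NON_POSITIVE_LABEL
        return out
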