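"""Internal-standard calibration curves, LOD/LOQ and precision/accuracy QC.

Calibration fits a least-squares line of response ratio (analyte /
internal standard) against nominal concentration, with 1/x weighting by
default since MS responses are heteroscedastic across a four-decade
linear range. Detection limits follow the slope rule

    LOD = 3.3 * sd_res / slope,    LOQ = 10 * sd_res / slope,

so LOQ/LOD = 10/3.3 by construction. Precision is the replicate CV
(100 * sd / mean) and accuracy error the relative bias
(100 * |mean - nominal| / nominal).

The assay validation figures of the reference method (per-analyte
precision, accuracy, LOD, LOQ and linearity range) ship as annotation
metadata via :func:`reference_assay_metrics`; they are stored values
for report annotation, not recomputed quantities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "QcSummary",
    "fit_calibration",
    "lod_loq",
    "qc_summary",
    "reference_assay_metrics",
    "load_calibration_points",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response line for one analyte."""

    analyte: str
    nominal: np.ndarray
    response: np.ndarray
    slope: float
    intercept: float
    residual_sd: float
    weighting: str

    @property
    def linear_range(self) -> tuple[float, float]:
        return float(self.nominal.min()), float(self.nominal.max())

    def predict(self, nominal):
        return self.intercept + self.slope * np.asarray(nominal, dtype=float)


def fit_calibration(points, analyte: str = "", weighting: str = "1/x") -> CalibrationCurve:
    """Fit response ratio vs nominal concentration.

    ``points`` is a sequence of (nominal ng/mL, response ratio) pairs;
    duplicate nominal levels are accepted and pooled. ``weighting`` is
    ``"1/x"`` (default) or ``"none"``. The residual sd is the unweighted
    root mean square residual with n-2 degrees of freedom.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (nominal, response) pairs")
    if len(pts) < 3:
        raise ValueError("need at least three calibration points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValueError("nominal concentrations must be positive")
    if np.ptp(x) == 0:
        raise ValueError("calibration needs at least two distinct nominal levels")
    if weighting == "1/x":
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sw = np.sqrt(w)
    A = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    intercept, slope = np.linalg.lstsq(A, y * sw, rcond=None)[0]
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return CalibrationCurve(
        analyte=analyte, nominal=x, response=y,
        slope=float(slope), intercept=float(intercept),
        residual_sd=residual_sd, weighting=weighting,
    )


def lod_loq(curve: CalibrationCurve) -> tuple[float, float]:
    """Slope-rule detection limits: (3.3 sd / slope, 10 sd / slope)."""
    if curve.slope <= 0:
        raise ValueError("LOD/LOQ require a positive calibration slope")
    lod = 3.3 * curve.residual_sd / curve.slope
    loq = 10.0 * curve.residual_sd / curve.slope
    return float(lod), float(loq)


@dataclass(frozen=True)
class QcSummary:
    """Replicate precision (CV %) and accuracy error (%) vs nominal."""

    analyte: str
    n: int
    mean: float
    precision_pct: float
    accuracy_error_pct: float


def qc_summary(replicates, nominal: float, analyte: str = "") -> QcSummary:
    x = np.asarray(replicates, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two replicates")
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    mean = float(x.mean())
    precision = 100.0 * float(x.std(ddof=1)) / mean if mean != 0 else float("inf")
    accuracy = 100.0 * abs(mean - nominal) / nominal
    return QcSummary(analyte, len(x), mean, precision, accuracy)


def reference_assay_metrics() -> pd.DataFrame:
    """Stored per-analyte validation figures of the reference assay.

    Columns: internal-standard variation %, intraday/interday precision
    and accuracy %, LOD/LOQ (ng/mL) and linearity range. Annotation
    metadata only — not recomputed from raw replicates.
    """
    text = resources.files("steroidratio.data").joinpath("assay_reference.csv").read_text(
        encoding="utf-8"
    )
    return pd.read_csv(io.StringIO(text)).set_index("analyte")


def load_calibration_points(path) -> dict[str, np.ndarray]:
    """Read delimited calibration points (analyte, level, nominal, response)."""
    frame = pd.read_csv(path)
    required = {"analyte", "nominal", "response"}
    if not required <= set(frame.columns):
        raise ValueError(f"calibration file needs columns {sorted(required)}")
    return {
        a: g[["nominal", "response"]].to_numpy(dtype=float)
        for a, g in frame.groupby("analyte")
    }
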