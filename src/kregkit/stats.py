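"""Error-analysis suite for predicted vs reference values and gradients.

For N estimates y_hat against references y the report carries MAE, mean
signed error (MSE), RMSE, means of both series, the largest positive and
negative outliers of y_hat - y (with their indices), and the least-squares
regression y_hat = a + b y with standard errors, correlation coefficient R
and R^2.

Degenerate inputs (fewer than 2 points, or zero variance in y or y_hat) make
the regression block undefined; those fields are set to the typed
:data:`UNDEFINED` marker rather than NaN, and everything else is still
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = ["ErrorReport", "error_report", "gradient_rmse", "UNDEFINED", "Undefined"]


class Undefined:
    """Typed marker for statistics that are undefined on degenerate input."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = Undefined()


@dataclass
class ErrorReport:
    n: int
    mae: float
    mse: float  # mean signed error
    rmse: float
    mean_estimated: float
    mean_reference: float
    largest_positive_outlier: float
    largest_positive_outlier_index: int
    largest_negative_outlier: float
    largest_negative_outlier_index: int
    a: float | Undefined = UNDEFINED
    b: float | Undefined = UNDEFINED
    se_a: float | Undefined = UNDEFINED
    se_b: float | Undefined = UNDEFINED
    r: float | Undefined = UNDEFINED
    r_squared: float | Undefined = UNDEFINED

    @property
    def regression_defined(self) -> bool:
        return not isinstance(self.b, Undefined)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def format(self) -> str:
        """Plain-text statistics block."""
        def fmt(v):
            return "undefined" if isinstance(v, Undefined) else f"{v:.10g}"

        lines = [
            f"Statistical analysis of {self.n} points",
            f"  MAE  = {self.mae:.10g}",
            f"  MSE  = {self.mse:.10g}",
            f"  RMSE = {self.rmse:.10g}",
            f"  mean(y_est) = {self.mean_estimated:.10g}",
            f"  mean(y_ref) = {self.mean_reference:.10g}",
            f"  largest positive outlier = {self.largest_positive_outlier:.10g}"
            f" (index {self.largest_positive_outlier_index})",
            f"  largest negative outlier = {self.largest_negative_outlier:.10g}"
            f" (index {self.largest_negative_outlier_index})",
            f"  regression y_est = a + b*y_ref:",
            f"    a  = {fmt(self.a)}   SE(a) = {fmt(self.se_a)}",
            f"    b  = {fmt(self.b)}   SE(b) = {fmt(self.se_b)}",
            f"    R  = {fmt(self.r)}   R^2   = {fmt(self.r_squared)}",
        ]
        return "\n".join(lines)


def error_report(y_hat: np.ndarray, y: np.ndarray) -> ErrorReport:
    """Full error report comparing estimates ``y_hat`` to references ``y``."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError("y_hat and y must have equal length")
    n = y.size
    if n == 0:
        raise ValueError("empty input")
    err = y_hat - y
    report = ErrorReport(
        n=n,
        mae=float(np.mean(np.abs(err))),
        mse=float(np.mean(err)),
        rmse=float(np.sqrt(np.mean(err**2))),
        mean_estimated=float(np.mean(y_hat)),
        mean_reference=float(np.mean(y)),
        largest_positive_outlier=float(np.max(err)),
        largest_positive_outlier_index=int(np.argmax(err)),
        largest_negative_outlier=float(np.min(err)),
        largest_negative_outlier_index=int(np.argmin(err)),
    )
    if n < 2:
        return report
    mu_y = report.mean_reference
    mu_yh = report.mean_estimated
    ss_yy = float(-n * mu_y**2 + np.sum(y**2))
    ss_hh = float(-n * mu_yh**2 + np.sum(y_hat**2))
    ss_yh = float(-n * mu_y * mu_yh + np.sum(y * y_hat))
    if ss_yy <= 0.0 or ss_hh <= 0.0:
        return report  # degenerate variance: regression block stays UNDEFINED
    b = ss_yh / ss_yy
    a = mu_yh - b * mu_y
    report.b = b
    report.a = a
    r2 = ss_yh**2 / (ss_yy * ss_hh)
    report.r_squared = min(r2, 1.0)
    report.r = math.copysign(math.sqrt(report.r_squared), ss_yh)
    if n > 2:
        s2 = (ss_hh - ss_yh**2 / ss_yy) / (n - 2)
        s = math.sqrt(max(s2, 0.0))
        report.se_a = s * math.sqrt(1.0 / n + mu_y**2 / ss_yy)
        report.se_b = s / math.sqrt(ss_yy)
    return report


def gradient_rmse(
    grad_hat: Sequence[np.ndarray], grad_ref: Sequence[np.ndarray]
) -> float:
    """RMSE over all Cartesian gradient components, each treated as a data point."""
    if len(grad_hat) != len(grad_ref):
        raise ValueError("gradient sequences differ in length")
    flat_hat, flat_ref = [], []
    for gh, gr in zip(grad_hat, grad_ref):
        gh = np.asarray(gh, dtype=float)
        gr = np.asarray(gr, dtype=float)
        if gh.shape != gr.shape:
            raise ValueError(f"gradient shape mismatch: {gh.shape} vs {gr.shape}")
        flat_hat.append(gh.ravel())
        flat_ref.append(gr.ravel())
    err = np.concatenate(flat_hat) - np.concatenate(flat_ref)
    return float(np.sqrt(np.mean(err**2)))
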