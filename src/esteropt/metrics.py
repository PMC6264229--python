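"""Model-validation statistics: RMSE, R² and absolute average deviation.

Conventions match the published study these tools reproduce:

* RMSE = sqrt(Σ (y_p − y_a)² / n), in conversion %.
* R² is the *squared Pearson correlation* of predicted vs actual — not the
  regression 1 − SSE/SST form.  Only the correlation form reproduces the
  study's printed test-set value from its printed pairs; it is invariant
  under affine rescaling of either vector, so a perfectly correlated but
  biased fit still scores 1.
* AAD = (100/n) Σ |y_p − y_a| / y_a, a mean relative deviation in %.
* relative_deviation compares a single validation measurement to a model
  prediction, with the prediction as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitMetrics", "aad", "evaluate", "r_squared", "relative_deviation", "rmse"]


@dataclass(frozen=True)
class FitMetrics:
    """RMSE / R² / AAD for one (predicted, actual) pair set of size n."""

    rmse: float
    r2: float
    aad: float
    n: int


def _pair(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size == 0 or a.size == 0:
        raise ValueError("empty input vectors")
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} predicted vs {a.size} actual")
    return p, a


def rmse(pred, actual) -> float:
    """Root mean squared error, in the response's units."""
    p, a = _pair(pred, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def r_squared(pred, actual) -> float:
    """Squared Pearson correlation between predictions and actuals."""
    p, a = _pair(pred, actual)
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        raise ValueError("r_squared undefined for a constant vector")
    return float(np.corrcoef(p, a)[0, 1] ** 2)


def aad(pred, actual) -> float:
    """Absolute average deviation in %, relative to the actual values.

    Asymmetric: actuals are the denominators and must be positive.
    """
    p, a = _pair(pred, actual)
    if np.any(a <= 0):
        raise ValueError("aad requires all actual values > 0")
    return float(100.0 * np.mean(np.abs(p - a) / a))


def relative_deviation(actual: float, predicted: float) -> float:
    """|actual − predicted| / predicted × 100, for a single validation run."""
    if not predicted > 0:
        raise ValueError(f"relative_deviation requires predicted > 0, got {predicted}")
    return float(100.0 * abs(actual - predicted) / predicted)


def evaluate(pred, actual) -> FitMetrics:
    """All three statistics for one pair set."""
    p, a = _pair(pred, actual)
    return FitMetrics(rmse=rmse(p, a), r2=r_squared(p, a), aad=aad(p, a), n=int(p.size))
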