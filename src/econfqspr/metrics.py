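"""Evaluation metrics for QSPR regression: R², MAE and Spearman rank
correlation (SpeaR), plus the acceptable-prediction count and the
pass/fail acceptance report used to judge a fitted model.

Conventions
-----------
R² = 1 − Σ(y_exp − y_pred)² / Σ(y_exp − ȳ_exp)²  (coefficient of
determination against the experimental mean; can be negative).

SpeaR uses the classical tie-free formula 1 − 6Σd²/(n(n²−1)) on the rank
differences; when either vector contains ties the Pearson correlation of
average-rank vectors is used instead (the two coincide when ranks are
distinct).

A model is conventionally regarded as predictive when test R² > 0.6,
SpeaR > 0.6 and MAE < 10% of the endpoint range; ``acceptance_report``
packages those checks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "r_squared",
    "mae",
    "spearman_rank",
    "acceptable_predictions",
    "MetricReport",
    "compute_report",
    "acceptance_report",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given input (e.g. zero-variance vector)."""


def _as_pair(y_exp, y_pred, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"expected equal-length 1-d vectors, got {a.shape} vs {b.shape}")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {a.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    return a, b


def r_squared(y_exp, y_pred) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    a, b = _as_pair(y_exp, y_pred, min_n=2)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("experimental values have zero variance")
    ss_res = float(np.sum((a - b) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(y_exp, y_pred) -> float:
    """Mean absolute error, in the units of the endpoint."""
    a, b = _as_pair(y_exp, y_pred, min_n=1)
    return float(np.mean(np.abs(a - b)))


def spearman_rank(y_exp, y_pred) -> float:
    """Spearman rank correlation.

    Tie-free inputs use 1 − 6Σd²/(n(n²−1)); ties fall back to the Pearson
    correlation of average ranks (identical result whenever ranks are
    distinct).
    """
    a, b = _as_pair(y_exp, y_pred, min_n=3)
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise UndefinedMetricError("rank correlation undefined for a constant vector")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = a.size
    ties = np.unique(a).size < n or np.unique(b).size < n
    if not ties:
        d2 = float(np.sum((ra - rb) ** 2))
        return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return float(np.corrcoef(ra, rb)[0, 1])


def acceptable_predictions(y_exp, y_pred, endpoint_range: Tuple[float, float]) -> int:
    """Count predictions with |error| strictly below 10% of the endpoint range."""
    a, b = _as_pair(y_exp, y_pred, min_n=1)
    lo, hi = float(endpoint_range[0]), float(endpoint_range[1])
    width = hi - lo
    if width <= 0:
        raise ValueError(f"endpoint range must have positive width, got {endpoint_range}")
    return int(np.sum(np.abs(a - b) < 0.10 * width))


@dataclass(frozen=True)
class MetricReport:
    """Bundle of the three metrics plus range-scaled error diagnostics."""

    r_squared: float
    mae: float
    spearman: float
    n: int
    endpoint_range: Tuple[float, float]
    mae_over_range: float  # percent
    acceptable_count: int

    def as_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        lo, hi = self.endpoint_range
        return (
            f"n={self.n}  R2={self.r_squared:.3f}  SpeaR={self.spearman:.3f}  "
            f"MAE={self.mae:.3f}  range=[{lo:.2f}, {hi:.2f}]  "
            f"MAE/range={self.mae_over_range:.2f}%  "
            f"acceptable={self.acceptable_count}/{self.n}"
        )


def compute_report(
    y_exp, y_pred, endpoint_range: Optional[Tuple[float, float]] = None
) -> MetricReport:
    """All metrics at once.

    ``endpoint_range`` defaults to the observed range of ``y_exp`` for the
    partition being scored (each partition is judged against its own range).
    """
    a, b = _as_pair(y_exp, y_pred, min_n=3)
    if endpoint_range is None:
        endpoint_range = (float(a.min()), float(a.max()))
    width = endpoint_range[1] - endpoint_range[0]
    if width <= 0:
        raise UndefinedMetricError("endpoint range has zero width")
    m = mae(a, b)
    return MetricReport(
        r_squared=r_squared(a, b),
        mae=m,
        spearman=spearman_rank(a, b),
        n=int(a.size),
        endpoint_range=endpoint_range,
        mae_over_range=100.0 * m / width,
        acceptable_count=acceptable_predictions(a, b, endpoint_range),
    )


def acceptance_report(report: MetricReport) -> dict:
    """Conventional pass/fail screen: R² > 0.6, SpeaR > 0.6, MAE < 10% of range."""
    checks = {
        "r_squared_gt_0.6": report.r_squared > 0.6,
        "spearman_gt_0.6": report.spearman > 0.6,
        "mae_lt_10pct_range": report.mae_over_range < 10.0,
    }
    checks["all_passed"] = all(checks.values())
    return checks
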