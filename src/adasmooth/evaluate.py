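"""Threshold scoring: RMSE of estimated regional rates against replicate baselines.

For each (stratum, threshold) the estimated regional rates over L replicates
are compared to the same replicates' baseline rates; thresholds are scored by
RMSE and their rate distributions summarised by five-number boxplot
statistics (linear-interpolation quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .simulate import BaselineRateSeries

__all__ = [
    "BoxStats",
    "distribution_summary",
    "rmse",
    "rmse_by_threshold",
    "population_weighted_rate",
]


@dataclass(frozen=True)
class BoxStats:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def distribution_summary(values: Iterable[float]) -> BoxStats:
    """Five-number summary with linear-interpolation quartiles."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return BoxStats(float(x.min()), float(q1), float(med), float(q3), float(x.max()))


def rmse(estimated: np.ndarray, baseline: np.ndarray) -> float:
    """sqrt(mean((estimated_l - baseline_l)^2)) over aligned replicates."""
    a = np.asarray(estimated, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"replicate mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_by_threshold(
    estimated: Mapping[str, Mapping[str, np.ndarray]],
    baseline: BaselineRateSeries,
    crude: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Evaluation table over (stratum, threshold).

    ``estimated`` maps stratum label -> threshold name -> array of regional
    rates over replicates, aligned with ``baseline``.  Columns: RMSE per
    100,000, boxplot statistics of the estimated rates, the baseline mean,
    and (optionally) the mean crude zone rate.
    """
    L = baseline.n_replicates
    rows = []
    for stratum, per_threshold in estimated.items():
        y = np.asarray(baseline.rates[stratum], dtype=float)
        crude_mean = (
            float(np.mean(crude[stratum])) if crude is not None and stratum in crude else np.nan
        )
        for name, y_hat in per_threshold.items():
            y_hat = np.asarray(y_hat, dtype=float)
            if y_hat.shape != (L,):
                raise AlignmentError(
                    f"{stratum}/{name}: expected {L} replicates, got {y_hat.shape}"
                )
            box = distribution_summary(y_hat)
            rows.append(
                {
                    "stratum": stratum,
                    "threshold_name": name,
                    "rmse_per_100k": rmse(y_hat, y),
                    "min": box.minimum,
                    "q1": box.q1,
                    "median": box.median,
                    "q3": box.q3,
                    "max": box.maximum,
                    "iqr": box.iqr,
                    "baseline_mean": float(y.mean()),
                    "crude_mean": crude_mean,
                }
            )
    return pd.DataFrame(rows)


def population_weighted_rate(rates: Iterable[float], populations: Iterable[float]) -> float:
    """Population-weighted mean rate: sum(rate_i * P_i) / sum(P_i)."""
    r = np.asarray(list(rates), dtype=float)
    p = np.asarray(list(populations), dtype=float)
    if r.shape != p.shape or r.size == 0:
        raise ValueError("rates and populations must be equal-length and nonempty")
    if p.sum() <= 0:
        raise ValueError("total population must be positive")
    return float(np.sum(r * p) / p.sum())
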