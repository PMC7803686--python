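"""Goodness-of-fit metrics and cross-treatment comparison arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "FitMetrics",
    "ComparisonRecord",
    "fit_metrics",
    "percent_difference",
    "quality_comparison",
    "initial_moisture_from_dry_fraction",
]


class FitMetrics(NamedTuple):
    """R^2, RMSE (units of the fitted variable) and AAD (%)."""

    r_squared: float
    rmse: float
    aad_percent: float


def fit_metrics(predicted, observed) -> FitMetrics:
    """Coefficient of determination, root-mean-square error and absolute
    average deviation between a prediction and an observation series.

    AAD is the mean of |predicted - observed| / observed in percent, so every
    observed value must be nonzero; R^2 is undefined for a constant observed
    series.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise DomainError(f"length mismatch: predicted {p.shape} vs observed {o.shape}")
    if p.size < 2:
        raise DomainError("need at least 2 points for fit metrics")
    if np.any(o == 0):
        raise DomainError("observed values must be nonzero for AAD")
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        raise DomainError("R^2 is undefined for a constant observed series")
    resid = p - o
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    aad = float(np.mean(np.abs(resid) / np.abs(o)) * 100.0)
    return FitMetrics(float(r2), rmse, aad)


def percent_difference(a: float, b: float) -> float:
    """(a - b) / b * 100: the signed difference of ``a`` relative to baseline ``b``."""
    if b == 0:
        raise DomainError("baseline value must be nonzero for a percent difference")
    return (a - b) / b * 100.0


@dataclass(frozen=True)
class ComparisonRecord:
    """One treatment-vs-baseline comparison of a single quality index."""

    label: str
    value_a: float
    value_b: float
    percent_difference: float
    absolute_difference: float

    def __post_init__(self):
        expected_pct = (self.value_a - self.value_b) / self.value_b * 100.0
        if abs(self.percent_difference - expected_pct) > 1e-9:
            raise DomainError("percent_difference inconsistent with its inputs")
        if abs(self.absolute_difference - (self.value_a - self.value_b)) > 1e-9:
            raise DomainError("absolute_difference inconsistent with its inputs")

    @classmethod
    def compute(cls, label: str, value_a: float, value_b: float) -> "ComparisonRecord":
        return cls(
            label=label,
            value_a=float(value_a),
            value_b=float(value_b),
            percent_difference=percent_difference(value_a, value_b),
            absolute_difference=float(value_a) - float(value_b),
        )


_DEFAULT_PAIRS = (("contact", "none"), ("airborne", "none"))


def quality_comparison(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = _DEFAULT_PAIRS,
) -> list[ComparisonRecord]:
    """Percent and absolute differences of every quality index for each
    (treatment, baseline) column pair of ``table``.

    By default compares contact sonication and airborne sonication against
    plain air drying.
    """
    records: list[ComparisonRecord] = []
    for treat, base in pairs:
        for col in (treat, base):
            if col not in table.columns:
                raise DomainError(f"treatment {col!r} not present in the quality table")
        for idx in table.index:
            records.append(
                ComparisonRecord.compute(
                    label=f"{idx}:{treat}_vs_{base}",
                    value_a=table.at[idx, treat],
                    value_b=table.at[idx, base],
                )
            )
    return records


def comparison_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of comparison records (percent rounded only on print)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "value_a": [r.value_a for r in records],
            "value_b": [r.value_b for r in records],
            "percent_difference": [r.percent_difference for r in records],
            "absolute_difference": [r.absolute_difference for r in records],
        }
    )


def initial_moisture_from_dry_fraction(f_dm: float) -> float:
    """Initial dry-basis moisture W0 = (1 - f_dm) / f_dm of the fresh material."""
    if not 0 < f_dm < 1:
        raise DomainError(f"dry-mass fraction must lie in (0, 1), got {f_dm}")
    return (1.0 - f_dm) / f_dm
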