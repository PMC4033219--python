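"""Misclassification accounting.

Overall rate: misclassified rows divided by the total sample size.
By-group rate: misclassified rows of a known group divided by that
group's size.  The group rates always recombine to the overall rate
through the group-size weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateResult",
    "misclassification_overall",
    "misclassification_by_group",
    "subgroup_ratio_increase",
]


@dataclass
class ReplicateResult:
    """Misclassification record of one (replicate, method, role)."""

    design_id: str
    replicate: int
    method: str
    role: str
    overall_rate: float
    group_rates: dict[int, float] = field(default_factory=dict)
    group_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall_rate <= 1.0:
            raise ValueError("overall_rate must lie in [0, 1]")
        weighted = sum(
            self.group_sizes[g] * r for g, r in self.group_rates.items()
        )
        total = sum(self.group_sizes.values())
        if total and abs(weighted / total - self.overall_rate) > 1e-12:
            raise ValueError("group rates do not recombine to the overall rate")


def _check_lengths(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"predicted and truth must have equal length, got {predicted.shape} vs {truth.shape}"
        )
    if predicted.size == 0:
        raise ValueError("cannot compute a rate over zero observations")
    return predicted, truth


def misclassification_overall(predicted, truth) -> float:
    """Fraction of observations assigned to the wrong group."""
    predicted, truth = _check_lengths(predicted, truth)
    return float(np.mean(predicted != truth))


def misclassification_by_group(predicted, truth) -> dict[int, float]:
    """Per-known-group misclassification fractions keyed by group label.

    A group absent from ``truth`` cannot have a rate; if requested via an
    empty group in the label universe it is flagged as NaN with a warning.
    """
    predicted, truth = _check_lengths(predicted, truth)
    rates: dict[int, float] = {}
    for g in np.unique(truth):
        mask = truth == g
        rates[int(g)] = float(np.mean(predicted[mask] != truth[mask]))
    return rates


def subgroup_ratio_increase(
    summary_equal: pd.DataFrame,
    summary_unequal: pd.DataFrame,
    keys: tuple[str, ...] = ("method", "overlap"),
    value: str = "rate",
) -> pd.DataFrame:
    """Change in mean misclassification from equal to unequal subgroup sizes.

    Both inputs are tidy summaries with one row per cell identified by
    ``keys`` and a mean-rate column ``value``; the result carries
    ``value`` = unequal - equal for every cell.  Negative entries are
    legitimate (a method can be *less* accurate with equal subgroups).
    """
    left = summary_equal.set_index(list(keys))[value]
    right = summary_unequal.set_index(list(keys))[value]
    missing = left.index.symmetric_difference(right.index)
    if len(missing):
        raise ValueError(f"summaries do not cover the same cells; mismatch at {list(missing)}")
    diff = (right - left).rename(value).reset_index()
    return diff
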