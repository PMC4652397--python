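"""Vulnerability response construction.

A mapping unit's ecologic radon risk is summarised by the 95th percentile of
its observed indoor radon concentrations (Bq m^-3).  For each threshold T in a
ladder of reference levels the unit is labelled ``high`` if P95 >= T and
``low`` otherwise, yielding one binary response per threshold.  Because every
label derives from the same P95, the label sets are nested: a unit high at T
is high at every lower threshold.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdLadder

__all__ = [
    "HIGH",
    "LOW",
    "percentile_95",
    "assign_vulnerability",
    "build_training_set",
    "label_column",
]

HIGH = "high"
LOW = "low"


def label_column(threshold: float) -> str:
    """Column name used for a threshold's label in tabular outputs."""
    t = float(threshold)
    return f"class_{t:g}"


def percentile_95(values: Iterable[float]) -> float:
    """95th percentile by linear interpolation of order statistics.

    Uses the plotting position h = (n - 1) * 0.95 + 1; a single observation is
    returned unchanged.

    Raises
    ------
    ValueError
        If ``values`` is empty or contains non-positive / non-finite entries.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the 95th percentile of an empty sample")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("radon concentrations must be positive and finite")
    return float(np.quantile(arr, 0.95, method="linear"))


def assign_vulnerability(p95: float, threshold: float) -> str:
    """Binary class for one unit at one threshold: ``high`` iff p95 >= threshold.

    A unit sitting exactly at the reference level is classed high, so a home
    measuring at the guideline is still flagged for action.
    """
    if p95 <= 0 or threshold <= 0:
        raise ValueError("p95 and threshold must be positive")
    return HIGH if p95 >= threshold else LOW


def build_training_set(
    units: pd.DataFrame,
    measurements: pd.DataFrame,
    ladder: ThresholdLadder | Sequence[float] = ThresholdLadder(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every measured unit at every threshold of the ladder.

    Parameters
    ----------
    units : DataFrame with a ``unit_id`` column.
    measurements : DataFrame with ``unit_id`` and ``concentration_bq_m3``.
    ladder : thresholds (Bq m^-3).

    Returns
    -------
    labels : DataFrame indexed like its ``unit_id`` column with ``p95`` and one
        ``class_<T>`` column per threshold; contains exactly the units having
        at least one measurement.
    distribution : DataFrame with one row per threshold: ``threshold``,
        ``n_high``, ``n_low``.
    """
    if not isinstance(ladder, ThresholdLadder):
        ladder = ThresholdLadder(tuple(ladder))
    if measurements.empty:
        raise ValueError("no unit has any radon measurement")
    known = set(units["unit_id"])
    unknown = set(measurements["unit_id"]) - known
    if unknown:
        raise ValueError(f"measurements reference unknown units: {sorted(unknown)[:5]}")

    p95 = (
        measurements.groupby("unit_id")["concentration_bq_m3"]
        .apply(percentile_95)
        .rename("p95")
    )
    labels = p95.reset_index()
    for t in ladder:
        labels[label_column(t)] = np.where(labels["p95"] >= t, HIGH, LOW)

    rows = []
    for t in ladder:
        n_high = int((labels[label_column(t)] == HIGH).sum())
        rows.append({"threshold": t, "n_high": n_high, "n_low": len(labels) - n_high})
    distribution = pd.DataFrame(rows)
    return labels, distribution
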