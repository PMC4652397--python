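"""Provincial mapping: threshold classifications, regional aggregation, and
population-at-risk estimation.

Unit populations are apportioned from parent census areas by area share and
kept fractional until final reporting; at every aggregation level (unit ->
parent -> region -> province) population is conserved.  Units whose covariate
levels were never seen in training are INELIGIBLE and their population is
reported separately, never folded into the low class.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .forest import INELIGIBLE, ForestResults, covariate_columns
from .vulnerability import HIGH, LOW

__all__ = [
    "apportion_population",
    "apportion_units",
    "build_threshold_maps",
    "summarize_regions",
    "population_fold_change",
]


def apportion_population(
    parent_population: float, parent_area: float, unit_area: float
) -> float:
    """Population share of one unit: parent_population * unit_area / parent_area.

    Real-valued; no rounding before aggregation, so per-parent shares sum
    exactly to the parent population.
    """
    if parent_area <= 0:
        raise ValueError("parent_area must be positive")
    if not 0 < unit_area <= parent_area:
        raise ValueError("unit_area must lie in (0, parent_area]")
    return parent_population * unit_area / parent_area


def apportion_units(units: pd.DataFrame) -> pd.Series:
    """Vectorised areal apportionment over a units table.

    Requires ``parent_population``, ``parent_area_km2`` and ``area_km2``.
    """
    if (units["area_km2"] > units["parent_area_km2"] + 1e-9).any():
        raise ValueError("unit area exceeds parent area")
    return (
        units["parent_population"] * units["area_km2"] / units["parent_area_km2"]
    ).rename("population")


def build_threshold_maps(
    results_by_threshold: Mapping[float, ForestResults],
    units: pd.DataFrame,
) -> pd.DataFrame:
    """One complete classification per threshold for every unit.

    Returns a frame indexed like ``units`` with ``unit_id`` and one
    ``class_<T>`` column per threshold taking values high / low / INELIGIBLE.
    Emits a warning (not an error) if the high fraction is not non-increasing
    in threshold — predicted maps need not nest exactly even though the
    training labels do.
    """
    X = units[covariate_columns(units)]
    out = pd.DataFrame({"unit_id": units["unit_id"].to_numpy()})
    fractions = []
    for t in sorted(results_by_threshold):
        pred = results_by_threshold[t].predict(X)
        out[f"class_{float(t):g}"] = pred.to_numpy()
        eligible = pred != INELIGIBLE
        fractions.append(
            (pred[eligible] == HIGH).mean() if eligible.any() else np.nan
        )
    if any(b > a + 1e-12 for a, b in zip(fractions, fractions[1:])):
        warnings.warn(
            "predicted high fraction is not non-increasing across thresholds",
            stacklevel=2,
        )
    return out


def summarize_regions(
    maps: pd.DataFrame,
    units: pd.DataFrame,
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Per region x threshold: area-weighted high fraction and populations by class.

    ``fraction_units_high`` is the high-classified share of regional area
    (ineligible area counts in the denominator).  ``population_high``,
    ``population_low`` and ``population_ineligible`` partition the regional
    population exactly.
    """
    if populations is None:
        populations = apportion_units(units)
    df = units[["unit_id", "region_id", "area_km2"]].copy()
    df["population"] = np.asarray(populations, dtype=float)
    unknown = df["region_id"].isna() | (df["region_id"] == "")
    if unknown.any():
        raise ValueError("every unit needs a region_id")
    df = df.merge(maps, on="unit_id", how="left", validate="one_to_one")

    class_cols = [c for c in maps.columns if c.startswith("class_")]
    rows = []
    for col in class_cols:
        t = float(col.split("_", 1)[1])
        if df[col].isna().any():
            raise ValueError(f"map {col} does not cover every unit")
        for region, g in df.groupby("region_id", sort=True):
            high = g[col] == HIGH
            low = g[col] == LOW
            inel = g[col] == INELIGIBLE
            rows.append(
                {
                    "region_id": region,
                    "threshold": t,
                    "fraction_units_high": float(
                        (g["area_km2"] * high).sum() / g["area_km2"].sum()
                    ),
                    "population_high": float(g.loc[high, "population"].sum()),
                    "population_low": float(g.loc[low, "population"].sum()),
                    "population_ineligible": float(g.loc[inel, "population"].sum()),
                }
            )
    return pd.DataFrame(rows).sort_values(["threshold", "region_id"], ignore_index=True)


def population_fold_change(
    summaries: pd.DataFrame, t_from: float, t_to: float
) -> float:
    """Ratio of province-wide high-class population at ``t_to`` vs ``t_from``.

    E.g. fold increase in the population at risk when the reference level is
    lowered from 200 to 50 Bq m^-3.
    """
    totals = summaries.groupby("threshold")["population_high"].sum()
    for t in (t_from, t_to):
        if float(t) not in totals.index:
            raise ValueError(f"threshold {t} not present in summaries")
    denom = totals.loc[float(t_from)]
    if denom == 0:
        raise ZeroDivisionError("no high-class population at the source threshold")
    return float(totals.loc[float(t_to)] / denom)
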