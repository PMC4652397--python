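"""Ecologic lung-cancer mortality trends.

Death records are filtered to natural causes (ICD-10 first letter outside
T..Y) among adults aged 20+, flagged as lung cancer when the cause starts
with C34, and assigned ecologic exposure strata: the radon vulnerability
class of their mapping unit at each threshold, a higher/lower smoking class
from the health area's prevalence relative to the median, and sex.  Within
each stratum the crude lung cancer mortality ratio — annual lung-cancer
deaths over annual all-natural deaths — is tabulated per year and smoothed
with a LOESS curve (tricube weights, local weighted least squares).

The misclassification sensitivity operation propagates assumed ecologic
misclassification fractions through the stratum counts by exact expected-count
arithmetic.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import LoessConfig, ThresholdLadder
from .forest import INELIGIBLE
from .vulnerability import HIGH, label_column

logger = logging.getLogger(__name__)

__all__ = [
    "HIGHER",
    "LOWER",
    "filter_deaths",
    "median_smoking_split",
    "assign_strata",
    "annual_ratio_series",
    "loess_smooth",
    "stratum_summary_table",
    "misclassification_sensitivity",
]

HIGHER = "higher"
LOWER = "lower"


def filter_deaths(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Restrict to natural-cause adult deaths and flag lung cancer.

    Drops records with age < 20, external causes (first cause-code letter in
    T..Y), or an empty/missing cause code (logged).  Returns the surviving
    records with a boolean ``lung`` column and a log of dropped counts.
    """
    df = records.copy()
    code = df["cause_code"].astype(str).str.strip().str.upper()
    malformed = code.eq("") | df["cause_code"].isna()
    if malformed.any():
        logger.warning("dropping %d records with malformed cause codes", malformed.sum())
    external = ~malformed & code.str[0].between("T", "Y")
    under_age = df["age"] < 20
    keep = ~(malformed | external | under_age)
    out = df.loc[keep].copy()
    out["lung"] = code[keep].str.startswith("C34")
    log = {
        "malformed": int(malformed.sum()),
        "external_cause": int((external & ~malformed).sum()),
        "under_20": int((under_age & ~malformed & ~external).sum()),
        "kept": int(keep.sum()),
    }
    return out, log


def median_smoking_split(prevalences: pd.Series | Mapping[str, float]) -> pd.Series:
    """Higher/lower smoking class per health area relative to the median.

    ``higher`` iff prevalence strictly exceeds the median of all estimates
    (midpoint convention for even counts); an area exactly at the median is
    ``lower``.
    """
    prev = pd.Series(prevalences, dtype=float)
    if len(prev) < 2:
        raise ValueError("need >= 2 health areas")
    if prev.isna().any():
        raise ValueError("missing smoking prevalence")
    med = float(np.median(prev.to_numpy()))
    return pd.Series(np.where(prev > med, HIGHER, LOWER), index=prev.index, name="smoking_class")


def assign_strata(
    deaths: pd.DataFrame,
    threshold_maps: pd.DataFrame,
    smoking_classes: pd.Series,
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Attach ecologic exposure strata to each (filtered) death.

    Adds one vulnerability-class column per threshold (values high / low /
    INELIGIBLE), and a ``smoking_class`` column from the death's health area.
    Deaths in INELIGIBLE units stay in the frame but are excluded from trend
    numerators and denominators downstream; the per-threshold counts of such
    deaths are returned as the exclusion log.
    """
    class_cols = [c for c in threshold_maps.columns if c.startswith("class_")]
    unmapped = set(deaths["unit_id"]) - set(threshold_maps["unit_id"])
    if unmapped:
        raise ValueError(f"deaths in unmapped units: {sorted(unmapped)[:5]}")
    out = deaths.merge(
        threshold_maps[["unit_id", *class_cols]], on="unit_id", how="left"
    )
    missing_ha = set(out["health_area_id"]) - set(smoking_classes.index)
    if missing_ha:
        raise ValueError(f"deaths in health areas without smoking class: {sorted(missing_ha)[:5]}")
    out["smoking_class"] = out["health_area_id"].map(smoking_classes)
    exclusions = {
        float(c.split("_", 1)[1]): int((out[c] == INELIGIBLE).sum()) for c in class_cols
    }
    return out, exclusions


def annual_ratio_series(
    stratified: pd.DataFrame,
    threshold: float,
    vulnerability: str,
    smoking: str | None = None,
    sex: str | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Crude lung cancer mortality ratio by year within one stratum.

    Returns a frame with ``year``, ``lung_deaths``, ``natural_deaths`` and
    ``ratio`` (NaN for years with no natural deaths).  ``years`` fixes the
    reported year axis; by default the observed span is used.
    """
    col = label_column(threshold)
    if col not in stratified.columns:
        raise ValueError(f"no map for threshold {threshold}")
    sel = stratified[col] == vulnerability
    if smoking is not None:
        sel &= stratified["smoking_class"] == smoking
    if sex is not None:
        sel &= stratified["sex"] == sex
    sub = stratified.loc[sel]
    if years is None:
        if sub.empty:
            logger.warning("empty stratum: threshold=%s class=%s", threshold, vulnerability)
            return pd.DataFrame(columns=["year", "lung_deaths", "natural_deaths", "ratio"])
        years = range(int(sub["year"].min()), int(sub["year"].max()) + 1)
    grouped = sub.groupby("year")
    nat = grouped.size().reindex(years, fill_value=0)
    lung = grouped["lung"].sum().reindex(years, fill_value=0).astype(int)
    out = pd.DataFrame(
        {
            "year": list(years),
            "lung_deaths": lung.to_numpy(),
            "natural_deaths": nat.to_numpy(),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(
            out["natural_deaths"] > 0, out["lung_deaths"] / out["natural_deaths"], np.nan
        )
    return out


def loess_smooth(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """LOESS fit evaluated at every ``x``.

    At each fit point the q = ceil(span * n) nearest observations (n counting
    non-missing y only) receive tricube weights w = (1 - (d/d_max)^3)^3 and a
    weighted least-squares polynomial of the given degree is fit; the fitted
    value at the point is returned.  Missing y values get a fitted value but
    do not participate in any local fit.
    """
    cfg = LoessConfig(span=span, degree=degree)  # validates span/degree
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d sequences")
    obs = np.isfinite(y) & np.isfinite(x)
    n = int(obs.sum())
    if n < cfg.degree + 2:
        raise ValueError(f"need >= {cfg.degree + 2} non-missing points")
    xf, yf = x[obs], y[obs]
    q = max(cfg.degree + 1, min(n, math.ceil(cfg.span * n)))

    fitted = np.empty_like(x)
    for i, x0 in enumerate(x):
        d = np.abs(xf - x0)
        dmax = np.partition(d, q - 1)[q - 1]
        if dmax == 0:
            fitted[i] = yf[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        if (w > 0).sum() < cfg.degree + 1:  # degenerate window: equal weights
            w = (d <= dmax).astype(float)
        sw = np.sqrt(w)
        V = np.vander(xf - x0, cfg.degree + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(V * sw[:, None], yf * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted


def stratum_summary_table(
    stratified: pd.DataFrame,
    ladder: ThresholdLadder | Sequence[float],
    from_rounded: bool = True,
) -> pd.DataFrame:
    """Study-period death counts and percentage ratios per ecologic stratum.

    One row for the higher-smoking stratum and one per-threshold row for the
    high-radon stratum: natural and lung death counts, each as a percent of
    the grand totals, and the ratio of the two percentages.  With
    ``from_rounded`` (default) the ratio is computed from the percentages as
    printed (1 decimal), then rounded to 2 decimals; otherwise from the raw
    counts.
    """
    if not isinstance(ladder, ThresholdLadder):
        ladder = ThresholdLadder(tuple(ladder))
    nat_total = len(stratified)
    lung_total = int(stratified["lung"].sum())
    if nat_total == 0:
        raise ValueError("no natural deaths to summarise")

    def row(name, threshold, mask):
        nat = int(mask.sum())
        lung = int(stratified.loc[mask, "lung"].sum())
        pct_nat = round(100.0 * nat / nat_total, 1)
        pct_lung = round(100.0 * lung / lung_total, 1) if lung_total else float("nan")
        if from_rounded:
            ratio = round(pct_lung / pct_nat, 2) if pct_nat else float("nan")
        else:
            ratio = (
                round((lung / lung_total) / (nat / nat_total), 2)
                if nat and lung_total
                else float("nan")
            )
        return {
            "stratum": name,
            "threshold": threshold,
            "natural_deaths": nat,
            "lung_deaths": lung,
            "pct_natural": pct_nat,
            "pct_lung": pct_lung,
            "ratio_of_percentages": ratio,
        }

    rows = [
        {
            "stratum": "total",
            "threshold": np.nan,
            "natural_deaths": nat_total,
            "lung_deaths": lung_total,
            "pct_natural": 100.0,
            "pct_lung": 100.0,
            "ratio_of_percentages": 1.0,
        },
        row("higher_smoking", np.nan, stratified["smoking_class"] == HIGHER),
    ]
    for t in sorted(ladder, reverse=True):
        rows.append(row("high_radon", t, stratified[label_column(t)] == HIGH))
    return pd.DataFrame(rows)


def misclassification_sensitivity(
    lung_high: float,
    other_high: float,
    lung_low: float,
    other_low: float,
    f_lung: float,
    f_other: float,
) -> tuple[float, float]:
    """Corrected crude mortality ratios under assumed ecologic misclassification.

    Moves ``f_lung`` of the high group's lung deaths and ``f_other`` of its
    other natural deaths into the low group (the low group is assumed
    correctly classified) and recomputes ratio_g = lung_g / (lung_g + other_g)
    on the moved expected counts.  Exact arithmetic; no resampling.
    """
    for v in (lung_high, other_high, lung_low, other_low):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    for f in (f_lung, f_other):
        if not 0.0 <= f <= 1.0:
            raise ValueError("misclassification fractions must lie in [0, 1]")
    if lung_high + other_high == 0:
        raise ValueError("empty high group")
    moved_lung = f_lung * lung_high
    moved_other = f_other * other_high
    lh, oh = lung_high - moved_lung, other_high - moved_other
    ll, ol = lung_low + moved_lung, other_low + moved_other
    if lh + oh == 0:
        raise ValueError("high group emptied by the correction")
    return lh / (lh + oh), ll / (ll + ol)
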