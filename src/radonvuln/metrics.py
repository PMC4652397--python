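"""Confusion-matrix metrics and spatial autocorrelation diagnostics.

Class accuracy is the proportion of an *observed* class correctly classified
(row-normalised); class precision is the proportion of a *predicted* class
correctly classified (column-normalised).  Cohen's kappa corrects overall
accuracy for chance agreement and is the headline comparison across
threshold models.  Geary's c (expectation 1 under spatial randomness, < 1 for
positive autocorrelation) with a permutation test checks whether the radon
response is spatially independent enough to treat units as exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .vulnerability import HIGH, LOW

__all__ = [
    "ConfusionMatrix",
    "class_accuracy",
    "class_precision",
    "cohen_kappa",
    "kappa_gain",
    "metric_report",
    "geary_c",
    "knn_weights",
]

CLASSES = (LOW, HIGH)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts indexed (observed, predicted) over (low, high)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("confusion matrix must be 2x2 with nonnegative counts")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_labels(cls, observed: Sequence[str], predicted: Sequence[str]) -> "ConfusionMatrix":
        obs = np.asarray(observed)
        pred = np.asarray(predicted)
        if obs.shape != pred.shape:
            raise ValueError("observed and predicted must align")
        c = np.zeros((2, 2), dtype=np.int64)
        for i, oc in enumerate(CLASSES):
            for j, pc in enumerate(CLASSES):
                c[i, j] = int(np.sum((obs == oc) & (pred == pc)))
        if c.sum() != obs.size:
            raise ValueError("labels outside {low, high}")
        return cls(c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _idx(self, cls_name: str) -> int:
        try:
            return CLASSES.index(cls_name)
        except ValueError:
            raise ValueError(f"unknown class {cls_name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(CLASSES, name="observed"),
                            columns=pd.Index(CLASSES, name="predicted"))


def class_accuracy(cm: ConfusionMatrix, cls_name: str) -> float | None:
    """Proportion of the observed class correctly classified; None if the class
    was never observed."""
    i = cm._idx(cls_name)
    row = cm.counts[i].sum()
    if row == 0:
        return None
    return float(cm.counts[i, i] / row)


def class_precision(cm: ConfusionMatrix, cls_name: str) -> float | None:
    """Proportion of the predicted class correctly classified; None if the class
    was never predicted."""
    j = cm._idx(cls_name)
    col = cm.counts[:, j].sum()
    if col == 0:
        return None
    return float(cm.counts[j, j] / col)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e); 0 if p_e = 1."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / (n * n)
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def metric_report(cm: ConfusionMatrix) -> dict:
    """One Table-style row: per-class accuracy/precision plus kappa."""
    return {
        "accuracy_low": class_accuracy(cm, LOW),
        "precision_low": class_precision(cm, LOW),
        "accuracy_high": class_accuracy(cm, HIGH),
        "precision_high": class_precision(cm, HIGH),
        "kappa": cohen_kappa(cm),
    }


def kappa_gain(kappas_by_threshold: dict[float, float]) -> dict[float, float]:
    """Improvement of each threshold's kappa over the next-higher threshold.

    The highest threshold has gain 0 by convention.
    """
    thresholds = sorted(kappas_by_threshold, reverse=True)
    gains: dict[float, float] = {}
    for higher, lower in zip(thresholds, thresholds[1:]):
        gains[lower] = kappas_by_threshold[lower] - kappas_by_threshold[higher]
    gains[thresholds[0]] = 0.0
    return gains


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Symmetrised k-nearest-neighbour binary spatial weights on centroids.

    w_ij = 1 if j is among i's k nearest neighbours or vice versa; diagonal 0.
    """
    from sklearn.neighbors import NearestNeighbors

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need >= 2 points for neighbour weights")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, idx[:, 1:].ravel()] = 1.0
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return w


def _geary_stat(x: np.ndarray, w: np.ndarray, denom: float, wsum: float) -> float:
    diff2 = (x[:, None] - x[None, :]) ** 2
    return (x.size - 1) * float((w * diff2).sum()) / (2.0 * wsum * denom)


def geary_c(
    values: Sequence[float],
    weights: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Geary's c with a two-sided permutation p-value.

    c = (N-1) * sum_ij w_ij (x_i - x_j)^2 / (2 W sum_i (x_i - xbar)^2).

    The p-value relabels the values over the units ``n_permutations`` times and
    applies the add-one correction (r + 1) / (B + 1), doubled and capped at 1
    for two-sidedness.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 units")
    if w.shape != (n, n) or not np.allclose(w, w.T):
        raise ValueError("weights must be a symmetric n x n matrix")
    if np.any(np.diag(w) != 0) or np.any(w < 0):
        raise ValueError("weights must be nonnegative with zero diagonal")
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("weights must have positive total")
    denom = float(((x - x.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("Geary's c undefined for constant values")

    c_obs = _geary_stat(x, w, denom, wsum)
    if n_permutations <= 0:
        return c_obs, float("nan")
    rng = np.random.default_rng(seed)
    r_low = 0
    r_high = 0
    for _ in range(n_permutations):
        c_perm = _geary_stat(rng.permutation(x), w, denom, wsum)
        if c_perm <= c_obs:
            r_low += 1
        if c_perm >= c_obs:
            r_high += 1
    p = 2.0 * min(r_low + 1, r_high + 1) / (n_permutations + 1)
    return c_obs, float(min(p, 1.0))
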