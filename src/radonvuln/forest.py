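"""Class-balanced bootstrap forest with out-of-bag evaluation.

The classifier behind each threshold map is an ensemble of maximally grown
binary classification trees.  Each tree is fit on a *balanced* bootstrap: n_min
draws with replacement from each class, where n_min is the minority class
size, so rare high-vulnerability units carry the same weight as the abundant
low ones.  Observations left out of a tree's bootstrap are out-of-bag (OOB)
for it; pooling OOB votes across all trees (and across independently seeded
runs) gives an internal, unbiased estimate of predictive performance without a
holdout set.

Splits are axis-aligned and chosen to maximise Gini impurity decrease.
Continuous covariates split at midpoints between consecutive observed values.
Categorical covariates are split over binary partitions of their observed
levels; for a binary response the optimal partition is found by sorting levels
by their within-node high-class proportion and scanning the resulting order,
which is exact without enumerating all subsets.

Usage follows the model/results convention::

    model = VulnerabilityForest(X, y, config=ForestConfig(seed=1))
    res = model.fit()
    res.kappa, res.confusion_matrix, res.summary()
    res.predict(province_X)        # 'high' / 'low' / 'INELIGIBLE'

A unit is INELIGIBLE for prediction when any categorical covariate takes a
level never observed in the training data: the forest has no evidence for it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ForestConfig, substream
from .metrics import ConfusionMatrix, metric_report
from .vulnerability import HIGH, LOW

__all__ = [
    "INELIGIBLE",
    "FeatureSchema",
    "VulnerabilityForest",
    "ForestResults",
    "balanced_bootstrap",
    "covariate_columns",
]

INELIGIBLE = "INELIGIBLE"

_LEAF = -1


class SchemaError(KeyError):
    """A prediction frame does not carry the model's covariate schema."""


def covariate_columns(frame: pd.DataFrame) -> list[str]:
    """Covariate columns in a units table: geology plus every ``cov_*`` column."""
    cols = [c for c in frame.columns if c == "geology" or c.startswith("cov_")]
    if not cols:
        raise SchemaError("no covariate columns (geology / cov_*) found")
    return cols


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered covariate names, kinds, and categorical level vocabularies."""

    names: tuple[str, ...]
    is_categorical: tuple[bool, ...]
    levels: tuple[tuple[str, ...] | None, ...]

    @classmethod
    def infer(cls, X: pd.DataFrame) -> "FeatureSchema":
        names, cats, levels = [], [], []
        for col in X.columns:
            s = X[col]
            if s.isna().any():
                raise ValueError(f"covariate {col!r} has missing values (unsupported)")
            names.append(col)
            if pd.api.types.is_numeric_dtype(s) and not isinstance(
                s.dtype, pd.CategoricalDtype
            ):
                cats.append(False)
                levels.append(None)
            else:
                cats.append(True)
                levels.append(tuple(sorted(map(str, s.unique()))))
        return cls(tuple(names), tuple(cats), tuple(levels))

    def encode(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Encode a frame to a float matrix plus an eligibility mask.

        Categorical columns become integer level codes; rows whose code is
        unseen in training are marked ineligible.
        """
        missing = [n for n in self.names if n not in X.columns]
        if missing:
            raise SchemaError(f"missing covariate columns: {missing}")
        n = len(X)
        mat = np.empty((n, len(self.names)), dtype=np.float64)
        eligible = np.ones(n, dtype=bool)
        for j, (name, cat, lv) in enumerate(
            zip(self.names, self.is_categorical, self.levels)
        ):
            col = X[name]
            if cat:
                codes = pd.Categorical(col.astype(str), categories=lv).codes
                eligible &= codes >= 0
                mat[:, j] = codes
            else:
                vals = pd.to_numeric(col).to_numpy(dtype=np.float64)
                eligible &= np.isfinite(vals)
                mat[:, j] = vals
        return mat, eligible


def balanced_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """In-bag index multiset: n_min draws with replacement from each class.

    ``y`` is a 0/1 vector; both classes must be present.  The in-bag size is
    2 * n_min; every index not drawn is OOB for the tree.
    """
    y = np.asarray(y)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("balanced bootstrap requires both classes present")
    n_min = min(idx0.size, idx1.size)
    return np.concatenate(
        [rng.choice(idx0, n_min, replace=True), rng.choice(idx1, n_min, replace=True)]
    )


def _plain_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    return rng.choice(n, n, replace=True)


# ---------------------------------------------------------------------------
# Tree growing


def _best_numeric_split(x, y, min_leaf):
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.cumsum(y[order])
    n = x.size
    nL = np.arange(1, n, dtype=np.float64)
    valid = xs[1:] > xs[:-1]
    if min_leaf > 1:
        valid &= (nL >= min_leaf) & ((n - nL) >= min_leaf)
    if not valid.any():
        return None
    n1L = c1[:-1].astype(np.float64)
    nR = n - nL
    n1R = c1[-1] - n1L
    with np.errstate(invalid="ignore"):
        score = n1L * (nL - n1L) / nL + n1R * (nR - n1R) / nR
    score[~valid] = np.inf
    i = int(np.argmin(score))
    lo, hi = xs[i], xs[i + 1]
    thr = 0.5 * (lo + hi)
    if not (lo < thr < hi):  # adjacent floats: fall back to the left value
        thr = lo
    return float(score[i]), float(thr)


def _best_categorical_split(codes, y, n_levels, min_leaf):
    cnt = np.bincount(codes, minlength=n_levels)
    cnt1 = np.bincount(codes, weights=y, minlength=n_levels)
    present = np.flatnonzero(cnt)
    if present.size < 2:
        return None
    # Optimal binary partition for Gini: scan levels ordered by class-1 share.
    order = np.argsort(cnt1[present] / cnt[present], kind="stable")
    lvl = present[order]
    cn = np.cumsum(cnt[lvl]).astype(np.float64)
    c1 = np.cumsum(cnt1[lvl])
    n = cn[-1]
    nL = cn[:-1]
    n1L = c1[:-1]
    valid = (nL >= min_leaf) & ((n - nL) >= min_leaf)
    if not valid.any():
        return None
    nR = n - nL
    n1R = c1[-1] - n1L
    with np.errstate(invalid="ignore"):
        score = n1L * (nL - n1L) / nL + n1R * (nR - n1R) / nR
    score[~valid] = np.inf
    i = int(np.argmin(score))
    return float(score[i]), np.sort(lvl[: i + 1]).astype(np.int64)


@dataclass
class _Tree:
    """Flat-array decision tree (arrays indexed by node id)."""

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left_levels: list[np.ndarray | None] = field(default_factory=list)
    children: list[tuple[int, int]] = field(default_factory=list)
    pred: list[int] = field(default_factory=list)

    def _new_node(self) -> int:
        self.feature.append(_LEAF)
        self.threshold.append(np.nan)
        self.left_levels.append(None)
        self.children.append((-1, -1))
        self.pred.append(1)
        return len(self.feature) - 1

    def predict(self, mat: np.ndarray) -> np.ndarray:
        out = np.empty(mat.shape[0], dtype=np.int8)
        stack = [(0, np.arange(mat.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[node]
            if f == _LEAF:
                out[idx] = self.pred[node]
                continue
            x = mat[idx, f]
            if self.left_levels[node] is not None:
                mask = np.isin(x.astype(np.int64), self.left_levels[node])
            else:
                mask = x <= self.threshold[node]
            l, r = self.children[node]
            stack.append((l, idx[mask]))
            stack.append((r, idx[~mask]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": list(map(int, self.feature)),
            "threshold": [None if np.isnan(t) else float(t) for t in self.threshold],
            "left_levels": [
                None if lv is None else list(map(int, lv)) for lv in self.left_levels
            ],
            "children": [list(c) for c in self.children],
            "pred": list(map(int, self.pred)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        t = cls(
            feature=list(d["feature"]),
            threshold=[np.nan if v is None else float(v) for v in d["threshold"]],
            left_levels=[
                None if lv is None else np.asarray(lv, dtype=np.int64)
                for lv in d["left_levels"]
            ],
            children=[tuple(c) for c in d["children"]],
            pred=list(d["pred"]),
        )
        return t


def _grow_tree(
    mat: np.ndarray,
    y: np.ndarray,
    in_bag: np.ndarray,
    is_cat: np.ndarray,
    n_levels: np.ndarray,
    mtry: int,
    min_leaf: int,
    rng: np.random.Generator,
) -> _Tree:
    tree = _Tree()
    d = mat.shape[1]
    root = tree._new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, in_bag)]
    while stack:
        node, idx = stack.pop()
        y_node = y[idx]
        n = idx.size
        n1 = int(y_node.sum())
        tree.pred[node] = 1 if 2 * n1 >= n else 0
        if n1 == 0 or n1 == n or n < max(2, 2 * min_leaf):
            continue
        feats = rng.choice(d, size=min(mtry, d), replace=False)
        best = None  # (score, feature, payload)
        for trial in (feats, None):
            scan = feats if trial is feats else np.arange(d)
            for f in scan:
                x = mat[idx, f]
                if is_cat[f]:
                    res = _best_categorical_split(
                        x.astype(np.int64), y_node, int(n_levels[f]), min_leaf
                    )
                else:
                    res = _best_numeric_split(x, y_node, min_leaf)
                if res is not None and (best is None or res[0] < best[0]):
                    best = (res[0], int(f), res[1])
            if best is not None:
                break  # mtry features sufficed; no full-scan fallback needed
        if best is None:
            continue  # no feature separates this node: leaf
        _, f, payload = best
        x = mat[idx, f]
        if is_cat[f]:
            tree.left_levels[node] = payload
            mask = np.isin(x.astype(np.int64), payload)
        else:
            tree.threshold[node] = payload
            mask = x <= payload
        tree.feature[node] = f
        lchild = tree._new_node()
        rchild = tree._new_node()
        tree.children[node] = (lchild, rchild)
        stack.append((lchild, idx[mask]))
        stack.append((rchild, idx[~mask]))
    return tree


# ---------------------------------------------------------------------------
# Model / Results


class VulnerabilityForest:
    """Balanced bootstrap forest model for one threshold's binary response.

    Parameters
    ----------
    X : DataFrame of mixed covariates (no missing values).
    y : sequence of 'high' / 'low' labels aligned with ``X``.
    config : ForestConfig.
    bootstrap : 'balanced' (default) or 'plain'; 'plain' is the conventional
        n-out-of-n bootstrap, kept as the comparison baseline under imbalance.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        config: ForestConfig | None = None,
        bootstrap: str = "balanced",
    ) -> None:
        if bootstrap not in ("balanced", "plain"):
            raise ValueError("bootstrap must be 'balanced' or 'plain'")
        y_arr = np.asarray(list(y))
        if len(y_arr) != len(X):
            raise ValueError("X and y must align")
        bad = set(np.unique(y_arr)) - {HIGH, LOW}
        if bad:
            raise ValueError(f"labels outside {{high, low}}: {sorted(bad)}")
        self.y01 = (y_arr == HIGH).astype(np.int8)
        if self.y01.min() == self.y01.max():
            raise ValueError("training data must contain both classes")
        counts = np.bincount(self.y01, minlength=2)
        if counts.min() < 2:
            raise ValueError("need >= 2 units per class")
        self.schema = FeatureSchema.infer(X)
        self.mat, eligible = self.schema.encode(X)
        if not eligible.all():
            raise ValueError("training covariates contain non-finite values")
        self.config = config or ForestConfig()
        self.bootstrap = bootstrap
        self._is_cat = np.asarray(self.schema.is_categorical)
        self._n_levels = np.asarray(
            [0 if lv is None else len(lv) for lv in self.schema.levels], dtype=np.int64
        )

    def fit(self) -> "ForestResults":
        cfg = self.config
        n = self.mat.shape[0]
        mtry = cfg.resolve_mtry(self.mat.shape[1])
        trees: list[_Tree] = []
        in_bag_counts: list[np.ndarray] = []
        oob_votes = np.zeros((n, 2), dtype=np.int64)
        sampler = balanced_bootstrap if self.bootstrap == "balanced" else _plain_bootstrap
        for run in range(cfg.n_runs):
            for t in range(cfg.n_trees_per_run):
                rng = substream(cfg.seed, 7, run, t)
                in_bag = sampler(self.y01, rng)
                tree = _grow_tree(
                    self.mat, self.y01, in_bag, self._is_cat, self._n_levels,
                    mtry, cfg.min_leaf_size, rng,
                )
                trees.append(tree)
                bag_count = np.bincount(in_bag, minlength=n)
                in_bag_counts.append(bag_count)
                oob_idx = np.flatnonzero(bag_count == 0)
                if oob_idx.size:
                    pred = tree.predict(self.mat[oob_idx])
                    np.add.at(oob_votes, (oob_idx, pred.astype(np.int64)), 1)
        covered = oob_votes.sum(axis=1) > 0
        if covered.mean() < 0.99:
            warnings.warn(
                f"only {covered.mean():.1%} of training units have OOB votes; "
                "grow more trees for a stable OOB estimate",
                stacklevel=2,
            )
        return ForestResults(self, trees, in_bag_counts, oob_votes)


class ForestResults:
    """Fitted forest: OOB evaluation, provincial prediction, serialization."""

    def __init__(
        self,
        model: VulnerabilityForest,
        trees: list[_Tree],
        in_bag_counts: list[np.ndarray],
        oob_votes: np.ndarray,
    ) -> None:
        self.model = model
        self.trees = trees
        self.in_bag_counts = in_bag_counts
        self.oob_votes = oob_votes

    # -- OOB evaluation ----------------------------------------------------

    @property
    def oob_covered(self) -> np.ndarray:
        """Mask of training units with at least one OOB vote."""
        return self.oob_votes.sum(axis=1) > 0

    @property
    def oob_predictions(self) -> np.ndarray:
        """OOB majority class per training unit (ties to high); uncovered
        units carry the empty string and are excluded from metrics."""
        votes = self.oob_votes
        pred = np.where(votes[:, 1] >= votes[:, 0], HIGH, LOW)
        out = np.asarray(pred, dtype=object)
        out[~self.oob_covered] = ""
        return out

    @property
    def confusion_matrix(self) -> ConfusionMatrix:
        m = self.oob_covered
        obs = np.where(self.model.y01 == 1, HIGH, LOW)[m]
        return ConfusionMatrix.from_labels(obs, self.oob_predictions[m])

    @property
    def kappa(self) -> float:
        from .metrics import cohen_kappa

        return cohen_kappa(self.confusion_matrix)

    def report(self) -> dict:
        rep = metric_report(self.confusion_matrix)
        rep["n_evaluated"] = int(self.oob_covered.sum())
        rep["n_trees"] = len(self.trees)
        return rep

    def summary(self) -> str:
        rep = self.report()
        cm = self.confusion_matrix.counts
        fmt = lambda v: "   --" if v is None else f"{v:5.3f}"
        lines = [
            "Balanced bootstrap forest — OOB evaluation",
            "==========================================",
            f"trees: {rep['n_trees']}   evaluated units: {rep['n_evaluated']}",
            "confusion matrix (rows observed, cols predicted; low, high):",
            f"    [[{cm[0,0]:6d} {cm[0,1]:6d}]",
            f"     [{cm[1,0]:6d} {cm[1,1]:6d}]]",
            f"accuracy  low: {fmt(rep['accuracy_low'])}   high: {fmt(rep['accuracy_high'])}",
            f"precision low: {fmt(rep['precision_low'])}   high: {fmt(rep['precision_high'])}",
            f"kappa: {rep['kappa']:6.3f}",
        ]
        return "\n".join(lines)

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Classify new units: 'high' / 'low', or 'INELIGIBLE' where any
        categorical covariate carries a level unseen in training."""
        mat, eligible = self.model.schema.encode(X)
        out = np.asarray([INELIGIBLE] * len(X), dtype=object)
        idx = np.flatnonzero(eligible)
        if idx.size:
            votes = np.zeros((idx.size, 2), dtype=np.int64)
            sub = mat[idx]
            for tree in self.trees:
                pred = tree.predict(sub)
                np.add.at(votes, (np.arange(idx.size), pred.astype(np.int64)), 1)
            out[idx] = np.where(votes[:, 1] >= votes[:, 0], HIGH, LOW)
        return pd.Series(out, index=X.index, name="class")

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "format": "radonvuln-forest-v1",
            "classes": [LOW, HIGH],
            "config": asdict(self.model.config),
            "bootstrap": self.model.bootstrap,
            "schema": {
                "names": list(self.model.schema.names),
                "is_categorical": list(self.model.schema.is_categorical),
                "levels": [
                    None if lv is None else list(lv) for lv in self.model.schema.levels
                ],
            },
            "y": [int(v) for v in self.model.y01],
            "oob_votes": self.oob_votes.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ForestResults":
        with open(path) as fh:
            doc = json.load(fh)
        model = VulnerabilityForest.__new__(VulnerabilityForest)
        model.config = ForestConfig(**doc["config"])
        model.bootstrap = doc["bootstrap"]
        model.schema = FeatureSchema(
            names=tuple(doc["schema"]["names"]),
            is_categorical=tuple(doc["schema"]["is_categorical"]),
            levels=tuple(
                None if lv is None else tuple(lv) for lv in doc["schema"]["levels"]
            ),
        )
        model.y01 = np.asarray(doc["y"], dtype=np.int8)
        model.mat = None
        trees = [_Tree.from_dict(d) for d in doc["trees"]]
        votes = np.asarray(doc["oob_votes"], dtype=np.int64)
        return cls(model, trees, [], votes)
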