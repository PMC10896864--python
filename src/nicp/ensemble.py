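"""Bagged regression trees mapping pulse-morphology features to ICP.

The learner is a bootstrap-aggregated ensemble of depth-limited CART
regression trees, written from scratch so its contract is fully testable:
every node exhaustively searches all features and all midpoints between
consecutive sorted unique values for the split minimizing the summed child
SSE (equivalently, weighted child variance); ties are broken toward the
lowest feature index, then the lowest threshold. Growth stops at the depth
cap (edges from the root), when a node cannot produce two children of
``min_leaf`` samples, or when the node target is constant. Leaves predict
the node mean, so predictions are convex combinations of training targets
and can never extrapolate beyond them.

The public face is :class:`BaggedTreeRegressor`, a scikit-learn compatible
estimator (``fit``/``predict``, ``get_params``/``set_params``) that composes
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .config import AnalysisConfig
from .core import FEATURE_NAMES, Dataset

__all__ = ["TreeNode", "fit_tree", "BaggedTreeRegressor", "fit_ensemble", "predict", "save_model", "load_model"]


@dataclass
class TreeNode:
    """A CART node: either a split (feature, threshold, children) or a leaf."""

    value: float
    n: int
    feature: int = -1
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        self._predict_into(X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[idx] = self.value
            return
        go_left = X[idx, self.feature] <= self.threshold
        self.left._predict_into(X, idx[go_left], out)  # type: ignore[union-attr]
        self.right._predict_into(X, idx[~go_left], out)  # type: ignore[union-attr]

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())  # type: ignore[union-attr]

    def to_dict(self) -> dict[str, Any]:
        if self.is_leaf:
            return {"value": self.value, "n": self.n}
        return {
            "value": self.value,
            "n": self.n,
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),  # type: ignore[union-attr]
            "right": self.right.to_dict(),  # type: ignore[union-attr]
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TreeNode":
        if "feature" not in d:
            return cls(value=d["value"], n=d["n"])
        return cls(
            value=d["value"],
            n=d["n"],
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[int, float, np.ndarray] | None:
    """Exhaustive search over all features and midpoint thresholds.

    Returns (feature, threshold, left_mask) for the split minimizing the
    summed child SSE, or None when no legal split exists. Strict-improvement
    comparison with features scanned in index order and thresholds ascending
    realizes the (lowest feature, lowest threshold) tie-break.
    """
    n = y.size
    best_sse = np.inf
    best: tuple[int, float] | None = None
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        ys = y[order]
        # split after position i (left = first i+1 samples); only between
        # distinct values and with both children >= min_leaf
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys * ys)
        total, total2 = csum[-1], csum2[-1]
        pos = np.arange(n - 1)
        legal = (xs[:-1] < xs[1:]) & (pos + 1 >= min_leaf) & (n - pos - 1 >= min_leaf)
        if not legal.any():
            continue
        p = pos[legal]
        nl = p + 1.0
        nr = n - nl
        sl, sl2 = csum[p], csum2[p]
        sse = (sl2 - sl * sl / nl) + ((total2 - sl2) - (total - sl) ** 2 / nr)
        k = int(np.argmin(sse))  # first minimum -> lowest threshold
        if sse[k] < best_sse:
            best_sse = float(sse[k])
            thr = 0.5 * (xs[p[k]] + xs[p[k] + 1])
            best = (j, float(thr))
    if best is None:
        return None
    j, thr = best
    return j, thr, X[:, j] <= thr


def fit_tree(
    X: np.ndarray, y: np.ndarray, max_depth: int = 8, min_leaf: int = 5
) -> TreeNode:
    """Grow one CART regression tree with greedy SSE-minimizing splits."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) and y (n,) with matching n")
    if y.size < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} samples to fit a tree")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("training data must be finite")
    return _grow(X, y, 0, max_depth, min_leaf)


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, min_leaf: int) -> TreeNode:
    node = TreeNode(value=float(np.mean(y)), n=int(y.size))
    if depth >= max_depth or y.size < 2 * min_leaf or np.ptp(y) == 0:
        return node
    found = _best_split(X, y, min_leaf)
    if found is None:
        return node
    j, thr, left_mask = found
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[left_mask], y[left_mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~left_mask], y[~left_mask], depth + 1, max_depth, min_leaf)
    return node


class BaggedTreeRegressor(RegressorMixin, BaseEstimator):
    """Bagged ensemble of depth-limited CART regression trees.

    Each of ``n_estimators`` trees is grown on an independent bootstrap
    resample of the training set (same size, with replacement); predictions
    are the per-row mean over trees. All features are available at every
    node of every tree.

    Parameters
    ----------
    n_estimators : int, default 30
        Number of trees in the ensemble.
    max_depth : int, default 8
        Depth cap per tree, counted in edges from the root.
    min_samples_leaf : int, default 5
        Minimum training rows in any leaf.
    random_state : int or None
        Seed for the bootstrap draws; fitting is deterministic given it.

    Attributes
    ----------
    trees_ : list of TreeNode
        Fitted tree roots.
    n_features_in_ : int
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    y_range_ : (float, float)
        Training-target extremes; predictions always fall inside.
    """

    def __init__(
        self,
        n_estimators: int = 30,
        max_depth: int = 8,
        min_samples_leaf: int = 5,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X: Any, y: Any) -> "BaggedTreeRegressor":
        X, y = validate_data(self, X, y, y_numeric=True, dtype=np.float64)
        if self.n_estimators < 1 or self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_estimators, max_depth and min_samples_leaf must be >= 1")
        n = y.size
        if n < 2 * self.min_samples_leaf:
            raise ValueError(
                f"need at least {2 * self.min_samples_leaf} training rows, got {n}"
            )
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            self.trees_.append(
                fit_tree(X[idx], y[idx], max_depth=self.max_depth, min_leaf=self.min_samples_leaf)
            )
        self.y_range_ = (float(np.min(y)), float(np.max(y)))
        return self

    def predict(self, X: Any) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = validate_data(self, X, reset=False, dtype=np.float64)
        preds = np.stack([tree.predict(X) for tree in self.trees_])
        return preds.mean(axis=0)

    # -- portable text serialization ------------------------------------
    def to_dict(self) -> dict[str, Any]:
        check_is_fitted(self, "trees_")
        return {
            "params": self.get_params(),
            "feature_names": list(getattr(self, "feature_names_", FEATURE_NAMES)),
            "y_range": list(self.y_range_),
            "trees": [t.to_dict() for t in self.trees_],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BaggedTreeRegressor":
        model = cls(**d["params"])
        model.trees_ = [TreeNode.from_dict(t) for t in d["trees"]]
        model.y_range_ = tuple(d["y_range"])  # type: ignore[assignment]
        model.n_features_in_ = len(d["feature_names"])
        model.feature_names_ = list(d["feature_names"])
        return model


def fit_ensemble(train: Dataset, cfg: AnalysisConfig, seed: int | None = None) -> BaggedTreeRegressor:
    """Fit the configured ensemble on a Dataset's observations."""
    X, y, _ = train.matrices()
    model = BaggedTreeRegressor(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_leaf,
        random_state=cfg.rng_seed if seed is None else seed,
    )
    model.fit(X, y)
    model.feature_names_ = list(FEATURE_NAMES)
    return model


def predict(model: BaggedTreeRegressor, X: np.ndarray | Dataset) -> np.ndarray:
    if isinstance(X, Dataset):
        X = X.matrices()[0]
    return model.predict(X)


def save_model(model: BaggedTreeRegressor, path: str | Path, cfg: AnalysisConfig | None = None) -> None:
    payload = model.to_dict()
    if cfg is not None:
        payload["config"] = cfg.to_dict()
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> BaggedTreeRegressor:
    return BaggedTreeRegressor.from_dict(json.loads(Path(path).read_text()))
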