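"""Regression-forest backend with out-of-bag bookkeeping.

Thin wrapper around :class:`sklearn.ensemble.RandomForestRegressor` exposing
the two things the ordinal methods need beyond a plain fit:

* averaged out-of-bag (OOB) predictions on the training rows, each computed
  only from trees whose bootstrap sample excluded that row; and
* fast per-tree numeric predictions for arbitrary new rows (one matrix
  column per tree), obtained by a leaf-lookup rather than repeated
  ``predict`` calls so that permutation-importance loops stay cheap.

Identical seed and data give bit-identical forests and predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["ForestModel", "fit_regression_forest"]


class ForestModel:
    """Fitted regression forest plus OOB structure.

    Attributes
    ----------
    forest : RandomForestRegressor
    n_trees : int
    n_train, p : int
        Training sample size and covariate count.
    oob_mask : ndarray of bool, shape (n_train, n_trees)
        True where the row was out of bag for the tree.
    oob_predictions : ndarray of shape (n_train,)
        Per-row average over OOB trees; NaN for rows that were in-bag in
        every tree (vanishingly rare for the recommended >= 500 trees).
    """

    def __init__(self, forest: RandomForestRegressor, X_train: np.ndarray):
        self.forest = forest
        self.n_train, self.p = X_train.shape
        self.n_trees = len(forest.estimators_)
        self._build_caches()
        self.oob_mask = self._compute_oob_mask()
        tree_preds = self.tree_predictions(X_train)
        self.oob_predictions = self.oob_masked_mean(tree_preds)

    # -- internals -----------------------------------------------------

    def _build_caches(self) -> None:
        self._tree_objs = [est.tree_ for est in self.forest.estimators_]
        self._leaf_values = [t.value[:, 0, 0] for t in self._tree_objs]

    def __getstate__(self):
        state = self.__dict__.copy()
        state.pop("_tree_objs", None)
        state.pop("_leaf_values", None)
        return state

    def __setstate__(self, state):
        self.__dict__.update(state)
        self._build_caches()

    def _compute_oob_mask(self) -> np.ndarray:
        mask = np.ones((self.n_train, self.n_trees), dtype=bool)
        for j, sample_idx in enumerate(self.forest.estimators_samples_):
            mask[sample_idx, j] = False
        return mask

    # -- prediction ----------------------------------------------------

    def tree_predictions(self, X) -> np.ndarray:
        """Numeric score prediction of every tree for every row (n x B)."""
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if X.ndim != 2 or X.shape[1] != self.p:
            raise ValueError(f"X must have {self.p} columns")
        out = np.empty((X.shape[0], self.n_trees), dtype=float)
        for j, (tree, vals) in enumerate(zip(self._tree_objs, self._leaf_values)):
            out[:, j] = vals[tree.apply(X)]
        return out

    def predict_mean(self, X) -> np.ndarray:
        """Forest-averaged numeric prediction (equals ``forest.predict``)."""
        return self.tree_predictions(X).mean(axis=1)

    def oob_masked_mean(self, tree_preds: np.ndarray) -> np.ndarray:
        """Average per training row over its OOB trees only.

        ``tree_preds`` must be aligned with the training rows.  Rows in-bag
        everywhere yield NaN.
        """
        if tree_preds.shape != (self.n_train, self.n_trees):
            raise ValueError("tree_preds must be n_train x n_trees")
        counts = self.oob_mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = np.where(
                counts > 0,
                (tree_preds * self.oob_mask).sum(axis=1) / np.maximum(counts, 1),
                np.nan,
            )
        return out


def fit_regression_forest(
    X,
    y_num,
    trees: int = 500,
    covariates_per_split: int | None = None,
    min_node_size: int = 5,
    seed: int | None = None,
) -> ForestModel:
    """Fit a bootstrap regression forest on numeric targets.

    ``covariates_per_split`` defaults to ``max(1, floor(p / 3))``, the
    conventional regression-forest choice; ``min_node_size`` is the minimum
    number of observations per leaf.
    """
    X = np.asarray(X, dtype=float)
    y_num = np.asarray(y_num, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-d matrix with at least two rows")
    if y_num.shape != (X.shape[0],):
        raise ValueError("y_num length must match X")
    if trees < 1:
        raise ValueError("need at least one tree")
    p = X.shape[1]
    if covariates_per_split is None:
        covariates_per_split = max(1, p // 3)
    if not 1 <= covariates_per_split <= p:
        raise ValueError("covariates_per_split must be in 1..p")
    forest = RandomForestRegressor(
        n_estimators=trees,
        max_features=covariates_per_split,
        min_samples_leaf=min_node_size,
        bootstrap=True,
        random_state=seed,
        n_jobs=None,
    )
    forest.fit(X, y_num)
    return ForestModel(forest, X)
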