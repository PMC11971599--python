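"""Score/border data model and the two ensemble prediction schemes.

Ordinal categories ``1..k`` are represented on a numeric score axis that is
partitioned by category borders ``b_1 <= ... <= b_{k+1}``.  A numeric
prediction falling into the r-th subinterval is labelled category ``r``.
Intervals are half-open, ``[b_r, b_{r+1})``, with the top interval closed —
so a partition of [0, 1] into five equal subintervals reads
``[0, .2), [.2, .4), [.4, .6), [.6, .8), [.8, 1]``.

Two ways of turning per-tree numeric score predictions into a single ordinal
label are provided:

* **TFAA** (transform-first-aggregate-after): each tree's numeric prediction
  is converted to a category, then the per-tree categories are combined by
  majority vote.
* **AFTA** (aggregate-first-transform-after): the tree predictions are
  averaged first and the single averaged score is converted once.

The two coincide for a single tree but can differ for ensembles, because the
vote discards within-interval information that the average retains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrdinalDataset",
    "ScorePartition",
    "TreeScoreMatrix",
    "midpoint_scores",
    "assign_category",
    "tfaa_predict",
    "afta_predict",
]


@dataclass
class OrdinalDataset:
    """Covariate matrix plus an integer-coded ordinal response.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Continuous or 0/1 binary covariates; no missing values.
    y : ndarray of shape (n,)
        Integer category labels in ``1..k``.
    k : int
        Number of ordinal categories (``k >= 2``).  Categories absent from
        ``y`` are allowed but must still lie within ``1..k``.
    covariate_names : list of str, optional
        Defaults to ``X1..Xp``.
    """

    X: np.ndarray
    y: np.ndarray
    k: int
    covariate_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("X must have at least one row and one column")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        y = np.asarray(self.y)
        if y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.all(y == np.floor(y)):
            raise ValueError("y must contain integer category labels")
        self.y = y.astype(int)
        if int(self.k) < 2:
            raise ValueError("k must be at least 2")
        self.k = int(self.k)
        if self.y.min() < 1 or self.y.max() > self.k:
            raise ValueError(f"y values must lie in 1..{self.k}")
        if self.covariate_names is None:
            self.covariate_names = [f"X{j + 1}" for j in range(self.p)]
        if len(self.covariate_names) != self.p:
            raise ValueError("covariate_names length must equal p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "OrdinalDataset":
        """Row subset (keeps ``k`` and covariate names)."""
        idx = np.asarray(idx)
        return OrdinalDataset(self.X[idx], self.y[idx], self.k, list(self.covariate_names))


@dataclass
class ScorePartition:
    """Category borders ``b_1..b_{k+1}`` and per-category scores ``s_1..s_k``."""

    borders: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.borders = np.asarray(self.borders, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.borders.ndim != 1 or self.scores.ndim != 1:
            raise ValueError("borders and scores must be 1-d")
        if len(self.borders) != len(self.scores) + 1:
            raise ValueError("need exactly one more border than scores")
        if np.any(np.diff(self.borders) < 0):
            raise ValueError("borders must be non-decreasing")
        if not self.borders[0] < self.borders[-1]:
            raise ValueError("first border must be strictly below the last")

    @property
    def k(self) -> int:
        return len(self.scores)

    @classmethod
    def from_borders(cls, borders) -> "ScorePartition":
        """Midpoint construction: ``s_r = (b_r + b_{r+1}) / 2``."""
        return cls(np.asarray(borders, dtype=float), midpoint_scores(borders))


@dataclass
class TreeScoreMatrix:
    """Per-observation, per-tree numeric score predictions (n_pred x B)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("tree score matrix must be 2-d (observations x trees)")
        if self.values.shape[1] < 1 or self.values.size == 0:
            raise ValueError("tree score matrix must contain at least one tree")
        if not np.isfinite(self.values).all():
            raise ValueError("tree scores must be finite")

    @property
    def n_pred(self) -> int:
        return self.values.shape[0]

    @property
    def n_trees(self) -> int:
        return self.values.shape[1]


def midpoint_scores(borders) -> np.ndarray:
    """Representative score of each category interval: the midpoint.

    ``borders`` must be strictly increasing; returns ``s_r = (b_r + b_{r+1})/2``
    for ``r = 1..k``, e.g. ``[0, .2, .4, .6, .8, 1] -> [.1, .3, .5, .7, .9]``.
    """
    b = np.asarray(borders, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise ValueError("borders must be a 1-d vector of length >= 2")
    if np.any(np.diff(b) <= 0):
        raise ValueError("invalid partition: borders must be strictly increasing")
    return (b[:-1] + b[1:]) / 2.0


def _as_tree_values(tree_scores) -> np.ndarray:
    if isinstance(tree_scores, TreeScoreMatrix):
        return tree_scores.values
    return TreeScoreMatrix(np.asarray(tree_scores, dtype=float)).values


def assign_category(value, borders) -> np.ndarray | int:
    """Map numeric score(s) to ordinal categories via the border partition.

    Uses the half-open convention ``[b_r, b_{r+1})`` with the top interval
    closed; values below ``b_1`` clip to category 1 and values above
    ``b_{k+1}`` clip to ``k``.  Duplicated interior borders (possible when
    quantile-derived borders tie) leave the corresponding empty interval
    unreachable, as the left-to-right scan intends.
    """
    b = np.asarray(borders, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise ValueError("borders must be a 1-d vector of length >= 2")
    if np.any(np.diff(b) < 0):
        raise ValueError("borders must be non-decreasing")
    if not b[0] < b[-1]:
        raise ValueError("first border must be strictly below the last")
    v = np.asarray(value, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("cannot assign a category to a non-finite value")
    # number of interior borders <= v, plus one; clips at both ends for free
    cat = np.searchsorted(b[1:-1], v, side="right") + 1
    if np.isscalar(value) or v.ndim == 0:
        return int(cat)
    return cat.astype(int)


def tfaa_predict(tree_scores, borders) -> np.ndarray:
    """Transform-first-aggregate-after: per-tree categories, majority vote.

    Each tree score is mapped through :func:`assign_category`; the modal
    category per observation is returned.  Vote ties break toward the lowest
    tied category, a fixed convention that keeps results reproducible.
    """
    values = _as_tree_values(tree_scores)
    cats = assign_category(values, borders)
    k = len(np.asarray(borders)) - 1
    n = cats.shape[0]
    counts = np.zeros((n, k), dtype=int)
    np.add.at(counts, (np.repeat(np.arange(n), cats.shape[1]), cats.ravel() - 1), 1)
    return np.argmax(counts, axis=1) + 1  # argmax takes the first (lowest) max


def afta_predict(tree_scores, borders) -> np.ndarray:
    """Aggregate-first-transform-after: average tree scores, then map once."""
    values = _as_tree_values(tree_scores)
    return assign_category(values.mean(axis=1), borders)
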