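"""Frequency-adjusted borders ordinal forest (fabOF).

fabOF trains a regression forest on the default category scores ``1..k`` and
then, instead of optimizing scores or borders, derives its category borders
from the forest's own out-of-bag (OOB) predictions: the interior border
``b_{r+1}`` is the empirical OOB-prediction quantile at the cumulative
relative frequency ``pi_r = #{y <= r} / n`` of the training response, and the
bounding borders are fixed at 1 and ``k`` (the smallest and largest score a
leaf mean can take).  Placing borders at those quantiles makes the
distribution of predicted categories approximate the training category
distribution, which implicitly assumes the training data represent the
population of interest.  Using OOB rather than in-sample predictions mimics
calibration on unseen data without sacrificing observations.

Prediction is aggregate-first-transform-after (AFTA): per-tree numeric
predictions for a new row are averaged and the average is mapped through the
learned borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np

from .core import OrdinalDataset, ScorePartition, afta_predict, assign_category
from .forest import ForestModel, fit_regression_forest

__all__ = [
    "FabOFModel",
    "frequency_adjusted_borders",
    "fit_fabof",
    "predict_fabof",
    "save_model",
    "load_model",
]


def frequency_adjusted_borders(oob_predictions, y, k: int) -> np.ndarray:
    """Borders ``[1, q_{pi_1}, ..., q_{pi_{k-1}}, k]`` from OOB predictions.

    ``q_p`` is the empirical quantile with linear interpolation between order
    statistics (matching R's default type-7 definition, so borders are
    reproducible across backends).  Categories missing from ``y`` give tied
    cumulative frequencies, hence duplicated borders, and are warned about;
    prediction stays well-defined because the empty interval is unreachable.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(y)
    oob = np.asarray(oob_predictions, dtype=float)
    if oob.shape != y.shape:
        raise ValueError("oob_predictions and y must have equal length")
    finite = np.isfinite(oob)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} observation(s) were in-bag in every tree; "
            "excluded from the border quantiles",
            stacklevel=2,
        )
        oob = oob[finite]
        if oob.size == 0:
            raise ValueError("no finite OOB predictions available")
    counts = np.bincount(y, minlength=k + 1)[1:]
    if np.any(counts == 0):
        warnings.warn(
            "some categories have zero training frequency; duplicated borders "
            "will make them unreachable",
            stacklevel=2,
        )
    pi = np.cumsum(counts)[:-1] / y.size
    interior = np.quantile(oob, np.minimum(pi, 1.0))  # linear interpolation
    # a cumulative frequency of exactly 1 means every category above is
    # empty; its border sits at the top of the score range so predictions
    # tied with max(oob) stay below it under the half-open convention
    interior = np.where(pi >= 1.0, float(k), interior)
    borders = np.concatenate(([1.0], np.clip(interior, 1.0, k), [float(k)]))
    return np.maximum.accumulate(borders)


@dataclass
class FabOFModel:
    """Fitted fabOF model: forest, learned borders, training frequencies."""

    forest: ForestModel
    partition: ScorePartition
    k: int
    cumulative_frequencies: np.ndarray  # pi_1..pi_{k-1}
    config: dict = field(default_factory=dict)
    covariate_names: list[str] | None = None

    @property
    def borders(self) -> np.ndarray:
        return self.partition.borders

    def predict(self, X_new) -> np.ndarray:
        """AFTA prediction: average the tree scores, map through borders."""
        return afta_predict(self.forest.tree_predictions(X_new), self.borders)

    def oob_categories(self) -> np.ndarray:
        """Training-set OOB predictions mapped through the learned borders."""
        oob = self.forest.oob_predictions
        return assign_category(oob[np.isfinite(oob)], self.borders)


def fit_fabof(
    dataset: OrdinalDataset,
    trees: int = 500,
    covariates_per_split: int | None = None,
    min_node_size: int = 5,
    seed: int | None = None,
) -> FabOFModel:
    """Fit fabOF: regression forest on scores ``1..k`` + OOB-quantile borders.

    No score or border optimization loop is run; the default scores are kept
    and the borders come from :func:`frequency_adjusted_borders`.
    """
    forest = fit_regression_forest(
        dataset.X,
        dataset.y.astype(float),  # default scores 1..k
        trees=trees,
        covariates_per_split=covariates_per_split,
        min_node_size=min_node_size,
        seed=seed,
    )
    borders = frequency_adjusted_borders(forest.oob_predictions, dataset.y, dataset.k)
    scores = np.arange(1, dataset.k + 1, dtype=float)
    counts = np.bincount(dataset.y, minlength=dataset.k + 1)[1:]
    pi = np.cumsum(counts)[:-1] / dataset.n
    return FabOFModel(
        forest=forest,
        partition=ScorePartition(borders, scores),
        k=dataset.k,
        cumulative_frequencies=pi,
        config={
            "trees": trees,
            "covariates_per_split": covariates_per_split,
            "min_node_size": min_node_size,
            "seed": seed,
        },
        covariate_names=list(dataset.covariate_names),
    )


def predict_fabof(model: FabOFModel, X_new) -> np.ndarray:
    """Functional alias for :meth:`FabOFModel.predict`."""
    return model.predict(X_new)


def save_model(model: FabOFModel, path) -> None:
    """Serialize a fitted model bundle; round-trips bit-identically."""
    joblib.dump({"format": "fabof-model", "version": 1, "model": model}, path)


def load_model(path) -> FabOFModel:
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or bundle.get("format") != "fabof-model":
        raise ValueError(f"{path} is not a fabOF model bundle")
    return bundle["model"]
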