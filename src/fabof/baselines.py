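"""Comparison methods for ordinal prediction benchmarks.

All predictors satisfy one contract — ``fit(dataset, seed) -> model`` with a
``predict(X) -> categories in 1..k`` method — so the experiment harness and
the importance machinery are method-agnostic:

* **naive OF**: regression forest on the default scores ``1..k`` with fixed
  half-integer borders ``0.5, 1.5, ..., k + 0.5``, predicting with either
  the vote-based (TFAA) or average-based (AFTA) scheme;
* **classification RF**: an ordinary classification forest that ignores
  ordinality;
* **RFSp** (split-based ordinal forest): ``k - 1`` binary forests for the
  events ``Y <= r``, combined through monotonized cumulative probabilities;
* **CLM**: the cumulative-logit proportional-odds model with all linear
  main effects.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .core import OrdinalDataset, ScorePartition, afta_predict, tfaa_predict
from .forest import ForestModel, fit_regression_forest
from .model import fit_fabof

__all__ = [
    "NaiveOFModel",
    "RFSpModel",
    "fit_naive_of",
    "fit_classification_rf",
    "fit_rfsp",
    "predict_rfsp",
    "fit_clm",
    "predict_clm",
    "PREDICTORS",
    "make_predictor",
]


def half_integer_borders(k: int) -> np.ndarray:
    """The naive-OF borders ``0.5, 1.5, ..., k + 0.5``."""
    return np.arange(k + 1) + 0.5


class NaiveOFModel:
    """Regression forest on default scores with fixed half-integer borders."""

    def __init__(self, forest: ForestModel, k: int, mode: str):
        if mode not in ("tfaa", "afta"):
            raise ValueError("mode must be 'tfaa' or 'afta'")
        self.forest = forest
        self.k = k
        self.mode = mode
        self.partition = ScorePartition(
            half_integer_borders(k), np.arange(1, k + 1, dtype=float)
        )

    def predict(self, X_new) -> np.ndarray:
        scores = self.forest.tree_predictions(X_new)
        if self.mode == "tfaa":
            return tfaa_predict(scores, self.partition.borders)
        return afta_predict(scores, self.partition.borders)


def fit_naive_of(
    dataset: OrdinalDataset,
    mode: str = "tfaa",
    trees: int = 500,
    covariates_per_split: int | None = None,
    min_node_size: int = 5,
    seed: int | None = None,
) -> NaiveOFModel:
    if mode not in ("tfaa", "afta"):
        raise ValueError("mode must be 'tfaa' or 'afta'")
    forest = fit_regression_forest(
        dataset.X,
        dataset.y.astype(float),
        trees=trees,
        covariates_per_split=covariates_per_split,
        min_node_size=min_node_size,
        seed=seed,
    )
    return NaiveOFModel(forest, dataset.k, mode)


class ClassificationRFModel:
    """Nominal classification forest; ties in the vote go to the lowest class."""

    def __init__(self, forest: RandomForestClassifier, k: int):
        self.forest = forest
        self.k = k

    def predict(self, X_new) -> np.ndarray:
        proba = self.forest.predict_proba(np.asarray(X_new, dtype=float))
        # classes_ are sorted ascending; argmax returns the first maximum
        return self.forest.classes_[np.argmax(proba, axis=1)].astype(int)


def fit_classification_rf(
    dataset: OrdinalDataset,
    trees: int = 500,
    covariates_per_split: int | None = None,
    min_node_size: int = 1,
    seed: int | None = None,
) -> ClassificationRFModel:
    p = dataset.p
    if covariates_per_split is None:
        covariates_per_split = max(1, int(np.floor(np.sqrt(p))))
    forest = RandomForestClassifier(
        n_estimators=trees,
        max_features=covariates_per_split,
        min_samples_leaf=min_node_size,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(dataset.X, dataset.y)
    return ClassificationRFModel(forest, dataset.k)


class RFSpModel:
    """k-1 binary forests for the cumulative events ``Y <= r``."""

    def __init__(self, forests: list[RandomForestClassifier], k: int):
        if len(forests) != k - 1:
            raise ValueError("need exactly k - 1 member forests")
        self.forests = forests
        self.k = k

    def cumulative_probabilities(self, X_new) -> np.ndarray:
        """Monotonized ``P(Y <= r | x)`` for r = 1..k (last column is 1)."""
        X_new = np.asarray(X_new, dtype=float)
        n = X_new.shape[0]
        cum = np.empty((n, self.k))
        for r, f in enumerate(self.forests):
            proba = f.predict_proba(X_new)
            if len(f.classes_) == 1:  # degenerate: indicator constant in training
                cum[:, r] = float(f.classes_[0])
            else:
                cum[:, r] = proba[:, list(f.classes_).index(1)]
        cum[:, -1] = 1.0
        return np.maximum.accumulate(cum, axis=1)  # enforce monotone in r

    def category_probabilities(self, X_new) -> np.ndarray:
        cum = self.cumulative_probabilities(X_new)
        return np.diff(np.hstack([np.zeros((cum.shape[0], 1)), cum]), axis=1)

    def predict(self, X_new) -> np.ndarray:
        return np.argmax(self.category_probabilities(X_new), axis=1) + 1


def fit_rfsp(
    dataset: OrdinalDataset,
    trees: int = 500,
    seed: int | None = None,
) -> RFSpModel:
    if dataset.k < 2:
        raise ValueError("RFSp requires k >= 2")
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(dataset.k - 1)]
    forests = []
    for r in range(1, dataset.k):
        target = (dataset.y <= r).astype(int)
        f = RandomForestClassifier(
            n_estimators=trees,
            bootstrap=True,
            random_state=child_seeds[r - 1],
        )
        f.fit(dataset.X, target)
        forests.append(f)
    return RFSpModel(forests, dataset.k)


def predict_rfsp(model: RFSpModel, X_new) -> np.ndarray:
    return model.predict(X_new)


class CLMModel:
    """Fitted proportional-odds (cumulative logit) model."""

    def __init__(self, result, k: int):
        self.result = result
        self.k = k

    def predict_probabilities(self, X_new) -> np.ndarray:
        return np.asarray(self.result.predict(np.asarray(X_new, dtype=float)))

    def predict(self, X_new) -> np.ndarray:
        # modal category; np.argmax breaks ties toward the lowest category
        return np.argmax(self.predict_probabilities(X_new), axis=1) + 1


def fit_clm(dataset: OrdinalDataset, seed: int | None = None) -> CLMModel:
    """Cumulative-logit model with all linear main effects.

    ``seed`` is accepted for contract uniformity; the fit is deterministic.
    """
    if dataset.n <= dataset.p:
        raise ValueError("CLM requires n > p")
    model = OrderedModel(dataset.y, dataset.X, distr="logit")
    try:
        result = model.fit(method="bfgs", maxiter=500, disp=False)
    except Exception as exc:  # pragma: no cover - rare numeric failures
        raise RuntimeError(f"CLM fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", True):
        raise RuntimeError("CLM did not converge (possible separation)")
    return CLMModel(result, dataset.k)


def predict_clm(model: CLMModel, X_new) -> np.ndarray:
    return model.predict(X_new)


class _FabOFPredictor:
    def __init__(self, **config):
        self.config = config
        self.model = None

    def fit(self, dataset: OrdinalDataset, seed: int | None = None):
        self.model = fit_fabof(dataset, seed=seed, **self.config)
        return self

    def predict(self, X):
        return self.model.predict(X)


class _NaiveOFPredictor:
    def __init__(self, mode: str, **config):
        self.mode = mode
        self.config = config
        self.model = None

    def fit(self, dataset, seed=None):
        self.model = fit_naive_of(dataset, mode=self.mode, seed=seed, **self.config)
        return self

    def predict(self, X):
        return self.model.predict(X)


class _ClassificationRFPredictor:
    def __init__(self, **config):
        self.config = config
        self.model = None

    def fit(self, dataset, seed=None):
        self.model = fit_classification_rf(dataset, seed=seed, **self.config)
        return self

    def predict(self, X):
        return self.model.predict(X)


class _RFSpPredictor:
    def __init__(self, **config):
        self.config = {k: v for k, v in config.items() if k == "trees"}
        self.model = None

    def fit(self, dataset, seed=None):
        self.model = fit_rfsp(dataset, seed=seed, **self.config)
        return self

    def predict(self, X):
        return self.model.predict(X)


class _CLMPredictor:
    def __init__(self, **config):
        self.model = None

    def fit(self, dataset, seed=None):
        self.model = fit_clm(dataset, seed=seed)
        return self

    def predict(self, X):
        return self.model.predict(X)


#: registry of predictor factories; each factory accepts shared forest
#: configuration keywords (unknown keywords are ignored where meaningless).
PREDICTORS = {
    "fabof": _FabOFPredictor,
    "naive_of_tfaa": lambda **cfg: _NaiveOFPredictor("tfaa", **cfg),
    "naive_of_afta": lambda **cfg: _NaiveOFPredictor("afta", **cfg),
    "rf_classification": _ClassificationRFPredictor,
    "rfsp": _RFSpPredictor,
    "clm": _CLMPredictor,
}


def make_predictor(name: str, **config):
    """Instantiate a registered predictor by name."""
    if name not in PREDICTORS:
        raise KeyError(f"unknown predictor '{name}'; choose from {sorted(PREDICTORS)}")
    return PREDICTORS[name](**config)
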