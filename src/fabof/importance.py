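"""Forest-level permutation variable importance for fabOF.

Because fabOF only turns numeric scores into ordinal labels after
aggregating across trees, importance cannot be computed tree by tree as in
classic forests.  Instead the whole permute-and-repredict cycle runs at the
forest level and is replicated ``reps`` times per covariate to stabilize the
estimate: for covariate ``j`` and replicate ``m``, column ``j`` is shuffled,
forest predictions are recomputed, and the importance replicate is the drop
in linearly weighted kappa relative to the unpermuted baseline.

Two evaluation modes are provided.  The default, ``"oob"``, scores
out-of-bag-style predictions on the training set (each observation predicted
only by trees that excluded it), mirroring how fabOF calibrates its borders
and avoiding optimism; ``"holdout"`` scores full-forest predictions on
user-supplied data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import assign_category
from .metrics import weighted_kappa
from .model import FabOFModel

__all__ = ["ImportanceResult", "permutation_vim", "plot_importance"]


@dataclass
class ImportanceResult:
    """Per-covariate permutation-importance replicates and summaries."""

    covariate_names: list[str]
    replicates: np.ndarray  # (p, reps)
    reps: int
    seed: int | None
    mode: str
    baseline: float

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.shape != (len(self.covariate_names), self.reps):
            raise ValueError("replicates must be p x reps")

    @property
    def median(self) -> np.ndarray:
        return np.median(self.replicates, axis=1)

    @property
    def q05(self) -> np.ndarray:
        return np.quantile(self.replicates, 0.05, axis=1)

    @property
    def q95(self) -> np.ndarray:
        return np.quantile(self.replicates, 0.95, axis=1)

    @property
    def mean(self) -> np.ndarray:
        return self.replicates.mean(axis=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "median": self.median,
                "q05": self.q05,
                "q95": self.q95,
                "mean": self.mean,
                "reps": self.reps,
            }
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def permutation_vim(
    model: FabOFModel,
    X,
    y,
    reps: int = 100,
    seed: int | None = None,
    mode: str = "oob",
    _permute=None,
) -> ImportanceResult:
    """Weighted-kappa permutation importance of every covariate.

    Parameters
    ----------
    model : FabOFModel
    X, y : evaluation data.  In ``"oob"`` mode these must be the training
        rows (the OOB masks are aligned with them); in ``"holdout"`` mode
        any conformable data work.
    reps : int
        Permutation replications per covariate (fresh shuffle each).
    seed : int, optional
        Seeds every shuffle; identical seed gives identical results.
    mode : {"oob", "holdout"}
    _permute : callable, optional
        Testing hook replacing the seeded shuffle; maps
        ``(rng, n) -> index array``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if mode not in ("oob", "holdout"):
        raise ValueError("mode must be 'oob' or 'holdout'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[1] != model.forest.p:
        raise ValueError(f"X must have {model.forest.p} columns")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X")
    n, p = X.shape
    forest = model.forest
    borders = model.borders

    if mode == "oob":
        if n != forest.n_train:
            raise ValueError("oob mode requires the training rows")
        oob_mask = forest.oob_mask
        counts = np.maximum(oob_mask.sum(axis=1), 1).astype(float)
        valid = np.isfinite(forest.oob_predictions)  # rows OOB for >= 1 tree
        baseline_cats = assign_category(forest.oob_predictions[valid], borders)
    else:
        oob_mask = None
        counts = np.full(n, forest.n_trees, dtype=float)
        valid = np.ones(n, dtype=bool)
        baseline_cats = model.predict(X)
    baseline = weighted_kappa(y[valid], baseline_cats, scheme="linear")

    rng = np.random.default_rng(seed)
    permute = _permute if _permute is not None else (lambda r, m: r.permutation(m))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    replicates = np.empty((p, reps))

    for j in range(p):
        # all replicates for covariate j stacked into one tall matrix so the
        # per-tree leaf lookup is amortized across replicates
        Xb = np.tile(X32, (reps, 1))
        col = X32[:, j]
        for m in range(reps):
            Xb[m * n : (m + 1) * n, j] = col[permute(rng, n)]
        Xb = np.ascontiguousarray(Xb)
        sums = np.zeros((reps, n))
        for t, (tree, vals) in enumerate(zip(forest._tree_objs, forest._leaf_values)):
            pv = vals[tree.apply(Xb)].reshape(reps, n)
            if oob_mask is not None:
                sums += pv * oob_mask[:, t]
            else:
                sums += pv
        mean = sums / counts
        cats = assign_category(mean, borders)
        kappas = np.array(
            [weighted_kappa(y[valid], cats[m][valid], scheme="linear") for m in range(reps)]
        )
        replicates[j] = baseline - kappas

    return ImportanceResult(
        covariate_names=list(model.covariate_names or [f"X{j+1}" for j in range(p)]),
        replicates=replicates,
        reps=reps,
        seed=seed,
        mode=mode,
        baseline=baseline,
    )


def plot_importance(result: ImportanceResult, ax=None):
    """5%-95% replicate range per covariate with a dot at the median."""
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 0.35 * len(result.covariate_names) + 1))
    order = np.argsort(result.median)
    ypos = np.arange(len(order))
    ax.hlines(ypos, result.q05[order], result.q95[order], color="grey", lw=2)
    ax.plot(result.median[order], ypos, "o", color="black")
    ax.set_yticks(ypos)
    ax.set_yticklabels([result.covariate_names[i] for i in order])
    ax.set_xlabel("importance (drop in linearly weighted kappa)")
    ax.axvline(0.0, color="lightgrey", lw=1, zorder=0)
    return ax
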