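"""Ordinal performance measures: weighted kappa, Kendall tau-b, Youden's J.

Weighted kappa penalizes disagreement proportionally to the distance between
true and predicted category; tau-b measures rank concordance with tie
corrections; the multiclass Youden index averages one-vs-rest
sensitivity + specificity - 1 over categories.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "confusion_table",
    "weighted_kappa",
    "kendall_tau_b",
    "youden_j_multiclass",
    "METRICS",
]


def _check_pair(y_true, y_pred):
    a = np.asarray(y_true).astype(int)
    b = np.asarray(y_pred).astype(int)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("y_true and y_pred must be equal-length 1-d vectors")
    if a.size < 1:
        raise ValueError("need at least one observation")
    if a.min() < 1 or b.min() < 1:
        raise ValueError("categories must be coded 1..k")
    return a, b


def confusion_table(y_true, y_pred, k: int | None = None) -> np.ndarray:
    """k x k count matrix ``o[i, j] = #{true i+1, predicted j+1}``."""
    a, b = _check_pair(y_true, y_pred)
    if k is None:
        k = int(max(a.max(), b.max()))
    if a.max() > k or b.max() > k:
        raise ValueError("labels exceed k")
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (a - 1, b - 1), 1)
    return table


def weighted_kappa(y_true, y_pred, scheme: str = "linear", k: int | None = None) -> float:
    """Cohen's weighted kappa with linear or quadratic disagreement weights.

    ``kappa_w = 1 - sum(v * o) / sum(v * e)`` where ``o`` are observed
    proportions, ``e = rowmarg x colmarg`` the chance-expected proportions,
    and ``v_ij = |i - j| / (k - 1)`` (linear) or its square (quadratic).
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    table = confusion_table(y_true, y_pred, k=k)
    k_eff = table.shape[0]
    if k_eff < 2:
        raise ValueError("weighted kappa needs at least two categories")
    o = table / table.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    i, j = np.indices((k_eff, k_eff))
    v = np.abs(i - j) / (k_eff - 1)
    if scheme == "quadratic":
        v = v**2
    denom = float((v * e).sum())
    if denom == 0.0:
        raise ValueError("weighted kappa undefined: degenerate marginals")
    return 1.0 - float((v * o).sum()) / denom


def kendall_tau_b(a, b) -> float:
    """Kendall's tau-b rank correlation with tie corrections."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("tau-b undefined for a constant vector")
    tau = stats.kendalltau(a, b, variant="b").statistic
    return float(tau)


def youden_j_multiclass(y_true, y_pred) -> float:
    """Mean one-vs-rest Youden index ``J_r = sens_r + spec_r - 1``.

    Categories absent from ``y_true`` are skipped with a warning (their
    sensitivity is undefined).
    """
    a, b = _check_pair(y_true, y_pred)
    k = int(max(a.max(), b.max()))
    js = []
    for r in range(1, k + 1):
        pos = a == r
        if not pos.any():
            warnings.warn(f"category {r} absent from y_true; skipped", stacklevel=2)
            continue
        neg = ~pos
        sens = (b[pos] == r).mean()
        spec = (b[neg] != r).mean() if neg.any() else 1.0
        js.append(sens + spec - 1.0)
    return float(np.mean(js))


METRICS = {
    "kappa_linear": lambda yt, yp: weighted_kappa(yt, yp, scheme="linear"),
    "kappa_quadratic": lambda yt, yp: weighted_kappa(yt, yp, scheme="quadratic"),
    "kendall": kendall_tau_b,
    "youden": youden_j_multiclass,
}
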