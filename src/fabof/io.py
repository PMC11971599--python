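"""CSV input/output for ordinal datasets and result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import OrdinalDataset

__all__ = [
    "read_ordinal_csv",
    "write_ordinal_csv",
    "write_results_csv",
    "bin_numeric",
]


def bin_numeric(values, upper_edges) -> np.ndarray:
    """Bin a numeric column into ordinal categories by inclusive upper edges.

    ``upper_edges`` are the top values of bins ``1..k-1``; everything above
    the last edge falls into category ``k``.  Grades 0-20 with edges
    ``[9, 11, 13, 15]`` give the five bins 0-9, 10-11, 12-13, 14-15, 16-20.
    """
    edges = np.asarray(upper_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("upper edges must be strictly increasing")
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("cannot bin non-finite values")
    return (np.searchsorted(edges, v, side="left") + 1).astype(int)


def read_ordinal_csv(
    path,
    response_column: str,
    category_levels: list | None = None,
    categorical_encoding: str = "onehot",
) -> OrdinalDataset:
    """Load a header CSV into an :class:`OrdinalDataset`.

    The response is mapped to ``1..k``: integer responses use their sorted
    unique values (already-``1..k``-coded data pass through unchanged);
    string-coded responses require an explicit ordered ``category_levels``
    list.  Non-numeric covariates are one-hot encoded (``"onehot"``) or
    integer coded by first appearance (``"integer"``).  Missing values are
    an error.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ValueError(f"response column '{response_column}' not in CSV")
    if df.isna().any().any():
        raise ValueError("CSV contains missing values")
    resp = df[response_column]
    if category_levels is not None:
        levels = list(category_levels)
        unknown = set(resp.unique()) - set(levels)
        if unknown:
            raise ValueError(f"unmappable response level(s): {sorted(map(str, unknown))}")
        y = resp.map({lev: i + 1 for i, lev in enumerate(levels)}).to_numpy()
        k = len(levels)
    else:
        if not pd.api.types.is_numeric_dtype(resp):
            raise ValueError(
                "string-coded responses need an ordered category_levels list"
            )
        uniq = np.sort(resp.unique())
        if not np.all(uniq == uniq.astype(int)):
            raise ValueError("numeric response values must be integers")
        y = resp.map({v: i + 1 for i, v in enumerate(uniq)}).to_numpy()
        k = len(uniq)
    cov = df.drop(columns=[response_column])
    if categorical_encoding not in ("onehot", "integer"):
        raise ValueError("categorical_encoding must be 'onehot' or 'integer'")
    non_numeric = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
    if non_numeric:
        if categorical_encoding == "onehot":
            cov = pd.get_dummies(cov, columns=non_numeric, drop_first=True, dtype=float)
        else:
            for c in non_numeric:
                cov[c] = pd.factorize(cov[c])[0].astype(float)
    return OrdinalDataset(
        cov.to_numpy(dtype=float), y, k, covariate_names=list(cov.columns)
    )


def write_ordinal_csv(dataset: OrdinalDataset, path, response_column: str = "y") -> None:
    df = pd.DataFrame(dataset.X, columns=dataset.covariate_names)
    df[response_column] = dataset.y
    df.to_csv(path, index=False)


def write_results_csv(results: pd.DataFrame, path) -> None:
    """Write a tidy benchmark result table (schema-stable, append-safe)."""
    results.to_csv(path, index=False)
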