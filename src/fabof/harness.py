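"""Experiment drivers: simulation study, importance study, CV benchmark.

Every driver is deterministic given its master seed: per-replication seeds
are spawned from a :class:`numpy.random.SeedSequence`, so the result tables
are bit-reproducible.  Per-replication method failures are recorded in the
result table (``status`` column) rather than aborting a long study.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .baselines import make_predictor
from .core import OrdinalDataset
from .importance import permutation_vim
from .metrics import METRICS
from .model import fit_fabof
from .simulation import DGPConfig, simulate_ordinal, sample_train_test

__all__ = ["run_simulation_study", "run_vim_study", "run_cv_benchmark"]

logger = logging.getLogger("fabof")


def _child_seeds(seed, count) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(count)]


def _score_all(y_true, y_pred, metrics) -> dict[str, float]:
    return {name: float(METRICS[name](y_true, y_pred)) for name in metrics}


def run_simulation_study(
    conditions,
    methods,
    replications: int = 1000,
    seed: int | None = None,
    metrics=("kappa_linear", "kappa_quadratic", "kendall"),
    method_config: dict | None = None,
) -> pd.DataFrame:
    """Simulate-fit-score loop over condition x replication x method.

    ``conditions`` is an iterable of dicts with keys understood by
    :class:`DGPConfig` (``dgp``, ``n``, ``k``, ``pattern``, ``sampling``,
    ...); ``methods`` are names from the predictor registry.  Each
    replication draws a fresh pool, splits it per the condition's sampling
    mode, fits every method on the training part and scores the test part
    with every metric.  Returns one tidy record per
    condition x replication x method x metric.
    """
    method_config = dict(method_config or {})
    conditions = [dict(c) for c in conditions]
    records = []
    seeds = _child_seeds(seed, len(conditions) * replications)
    si = 0
    for cond in conditions:
        for rep in range(replications):
            rep_seed = seeds[si]
            si += 1
            config = DGPConfig(**{**cond, "seed": rep_seed})
            pool = simulate_ordinal(config)
            train, test = sample_train_test(
                pool,
                config.n,
                stratified_train=(config.sampling == "stratified"),
                seed=rep_seed + 1,
            )
            for method in methods:
                base = {
                    **{k: cond.get(k) for k in ("dgp", "n", "k", "pattern", "sampling")},
                    "replication": rep,
                    "method": method,
                    "seed": rep_seed,
                }
                try:
                    t0 = time.perf_counter()
                    predictor = make_predictor(method, **method_config).fit(
                        train, seed=rep_seed + 2
                    )
                    fit_seconds = time.perf_counter() - t0
                    y_pred = predictor.predict(test.X)
                    scores = _score_all(test.y, y_pred, metrics)
                except Exception as exc:  # record, keep the study alive
                    logger.warning("replication %d, %s failed: %s", rep, method, exc)
                    for name in metrics:
                        records.append(
                            {**base, "metric": name, "value": np.nan,
                             "status": f"failed: {exc}", "fit_seconds": np.nan}
                        )
                    continue
                for name, value in scores.items():
                    records.append(
                        {**base, "metric": name, "value": value,
                         "status": "ok", "fit_seconds": fit_seconds}
                    )
    return pd.DataFrame.from_records(records)


def run_vim_study(
    dgp: int = 1,
    n_datasets: int = 100,
    n: int = 1000,
    trees: int = 500,
    reps: int = 100,
    seed: int | None = None,
    k: int = 5,
    pattern: str = "equal",
) -> pd.DataFrame:
    """Permutation-importance recovery study.

    Simulates ``n_datasets`` datasets of size ``n`` from the DGP, fits fabOF
    (``trees`` trees) on each, runs the weighted-kappa permutation VIM with
    ``reps`` replications, and summarizes the per-dataset median importance
    per covariate by its median and 5%/95% quantiles across datasets.
    """
    if dgp not in (1, 4):
        raise ValueError("the importance study is defined for DGP 1 and 4")
    seeds = _child_seeds(seed, n_datasets)
    per_dataset = []
    names = None
    for d, ds_seed in enumerate(seeds):
        config = DGPConfig(dgp=dgp, n=n, k=k, pattern=pattern, pool_size=n, seed=ds_seed)
        data = simulate_ordinal(config)
        model = fit_fabof(data, trees=trees, seed=ds_seed + 1)
        result = permutation_vim(model, data.X, data.y, reps=reps, seed=ds_seed + 2)
        per_dataset.append(np.median(result.replicates, axis=1))
        names = result.covariate_names
        logger.info("importance study: dataset %d/%d done", d + 1, n_datasets)
    values = np.asarray(per_dataset)  # (n_datasets, p)
    return pd.DataFrame(
        {
            "covariate": names,
            "median": np.median(values, axis=0),
            "q05": np.quantile(values, 0.05, axis=0),
            "q95": np.quantile(values, 0.95, axis=0),
            "mean": values.mean(axis=0),
            "n_datasets": n_datasets,
            "reps": reps,
        }
    )


def run_cv_benchmark(
    dataset: OrdinalDataset,
    methods,
    folds: int = 5,
    replications: int = 50,
    seed: int | None = None,
    metrics=("kappa_linear", "kappa_quadratic", "kendall"),
    method_config: dict | None = None,
    stratified: bool = True,
) -> pd.DataFrame:
    """Replicated k-fold cross-validation over all methods and metrics.

    Folds are category-stratified by default; each observation appears in
    exactly one test fold per replication.  Returns one record per
    replication x fold x method x metric.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    method_config = dict(method_config or {})
    seeds = _child_seeds(seed, replications)
    records = []
    for rep, rep_seed in enumerate(seeds):
        if stratified:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        else:
            from sklearn.model_selection import KFold

            splitter = KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold, (tr_idx, te_idx) in enumerate(splitter.split(dataset.X, dataset.y)):
            train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
            for method in methods:
                base = {
                    "replication": rep,
                    "fold": fold,
                    "method": method,
                    "seed": rep_seed,
                }
                try:
                    t0 = time.perf_counter()
                    predictor = make_predictor(method, **method_config).fit(
                        train, seed=rep_seed + fold
                    )
                    fit_seconds = time.perf_counter() - t0
                    scores = _score_all(test.y, predictor.predict(test.X), metrics)
                except Exception as exc:
                    logger.warning("rep %d fold %d %s failed: %s", rep, fold, method, exc)
                    for name in metrics:
                        records.append(
                            {**base, "metric": name, "value": np.nan,
                             "status": f"failed: {exc}", "fit_seconds": np.nan}
                        )
                    continue
                for name, value in scores.items():
                    records.append(
                        {**base, "metric": name, "value": value,
                         "status": "ok", "fit_seconds": fit_seconds}
                    )
    return pd.DataFrame.from_records(records)
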