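"""Synthetic ordinal data generators.

Four data-generating processes (DGPs) over ``p = 15`` uncorrelated standard
normal covariates, of which ``X1..X6`` are influential and ``X7..X15`` are
noise:

1. proportional odds with linear predictor ``g1`` (quadratic and sine terms
   mixed with linear ones);
2. linear regression ``g1(x) + N(0, 1)`` noise, binned into categories —
   the common "discretized continuous outcome" use-case;
3. proportional odds with the mixture predictor
   ``g(x) = 0.6 g1(x) + 0.4 g2(x)``;
4. as DGP 1 but with ``X5`` and ``X15`` replaced by Bernoulli(.5) binary
   covariates and the ``X5`` effect doubled from .5 to 1 to preserve its
   effect magnitude.

Two marginal response patterns are supported: ``"equal"`` (each category
1/k) and ``"wide_middle"`` (mass concentrated in the central categories,
default ``(.10, .20, .40, .20, .10)`` for k = 5).  Thresholds/binning
cut-points are calibrated empirically by pilot-sample quantile matching, so
any predictor configuration attains the requested pattern.

A study draws a large pool (default 10,000 observations) from which
train/test subsamples are taken; the training subsample may be drawn with
or without category stratification, the test subsample is always
stratified.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import OrdinalDataset

__all__ = [
    "PredictorCoefficients",
    "DGPConfig",
    "default_g1",
    "default_g2",
    "pattern_targets",
    "make_covariates",
    "linear_predictor",
    "calibrate_thresholds",
    "simulate_ordinal",
    "sample_train_test",
]

P_COVARIATES = 15


@dataclass(frozen=True)
class PredictorCoefficients:
    """Named coefficient set for one linear-predictor function.

    ``linear[j]`` multiplies ``X_{j+1}``; ``quadratic`` and ``sine`` hold
    ``(covariate index (0-based), coefficient)`` pairs for ``c * x**2`` and
    ``c * sin(2 x)`` terms.
    """

    linear: tuple[float, ...]
    quadratic: tuple[tuple[int, float], ...] = ()
    sine: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.linear) != P_COVARIATES:
            raise ValueError(f"linear must have {P_COVARIATES} entries")
        for idx, _ in (*self.quadratic, *self.sine):
            if not 0 <= idx < P_COVARIATES:
                raise ValueError("term references a covariate outside 1..15")

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != P_COVARIATES:
            raise ValueError(f"X must have {P_COVARIATES} columns")
        g = X @ np.asarray(self.linear)
        for idx, c in self.quadratic:
            g = g + c * X[:, idx] ** 2
        for idx, c in self.sine:
            g = g + c * np.sin(2.0 * X[:, idx])
        return g


def default_g1(dgp: int = 1) -> PredictorCoefficients:
    """Default first predictor: linear + quadratic + sine effects on X1..X6.

    The X5 coefficient is .5, raised to 1 for DGP 4 where X5 becomes binary.
    """
    x5 = 1.0 if dgp == 4 else 0.5
    linear = [1.0, 0.75, 0.0, 0.0, x5, 1.0] + [0.0] * 9
    return PredictorCoefficients(
        linear=tuple(linear),
        quadratic=((2, 0.5),),  # 0.5 * X3^2
        sine=((3, 1.0),),  # sin(2 * X4)
    )


def default_g2() -> PredictorCoefficients:
    """Default second predictor: all-linear with a distinct effect pattern."""
    linear = [0.5, 1.0, 1.0, 0.5, 1.0, 0.5] + [0.0] * 9
    return PredictorCoefficients(linear=tuple(linear))


def pattern_targets(pattern: str, k: int) -> np.ndarray:
    """Target marginal category proportions for a response pattern."""
    if pattern == "equal":
        return np.full(k, 1.0 / k)
    if pattern == "wide_middle":
        if k == 5:
            return np.array([0.10, 0.20, 0.40, 0.20, 0.10])
        # symmetric unimodal fallback for other k: triangular weights
        w = 1.0 + np.minimum(np.arange(k), np.arange(k)[::-1])
        return w / w.sum()
    raise ValueError("pattern must be 'equal' or 'wide_middle'")


@dataclass
class DGPConfig:
    """Configuration of one simulation condition."""

    dgp: int = 1
    n: int = 750
    k: int = 5
    pattern: str = "equal"
    g1: PredictorCoefficients | None = None
    g2: PredictorCoefficients | None = None
    mixture_weights: tuple[float, float] = (0.6, 0.4)
    pool_size: int = 10_000
    sampling: str = "stratified"
    noise_sd: float = 1.0  # residual SD of the DGP-2 regression outcome
    pilot_n: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dgp not in (1, 2, 3, 4):
            raise ValueError("dgp must be 1, 2, 3 or 4")
        if self.pattern not in ("equal", "wide_middle"):
            raise ValueError("pattern must be 'equal' or 'wide_middle'")
        if self.sampling not in ("stratified", "random"):
            raise ValueError("sampling must be 'stratified' or 'random'")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if self.pool_size < self.n:
            raise ValueError("pool size must be at least n")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.g1 is None:
            self.g1 = default_g1(self.dgp)
        if self.g2 is None:
            self.g2 = default_g2()

    @property
    def targets(self) -> np.ndarray:
        return pattern_targets(self.pattern, self.k)


def make_covariates(n: int, dgp: int = 1, seed=None) -> np.ndarray:
    """Draw the 15-column covariate matrix for a DGP.

    All columns are iid standard normal; DGP 4 replaces X5 and X15 with
    Bernoulli(.5) draws (the normal columns are drawn first, so for a shared
    seed the remaining 13 columns coincide with DGP 1's).
    """
    if dgp not in (1, 2, 3, 4):
        raise ValueError("dgp must be 1, 2, 3 or 4")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.standard_normal((n, P_COVARIATES))
    if dgp == 4:
        X[:, 4] = rng.binomial(1, 0.5, size=n)
        X[:, 14] = rng.binomial(1, 0.5, size=n)
    return X


def linear_predictor(
    X,
    which: str = "g1",
    coefficients: PredictorCoefficients | None = None,
    dgp: int = 1,
    g2: PredictorCoefficients | None = None,
    mixture_weights: tuple[float, float] = (0.6, 0.4),
) -> np.ndarray:
    """Evaluate ``g1``, ``g2`` or the mixture ``w1 g1 + w2 g2``."""
    if which not in ("g1", "g2", "mixture"):
        raise ValueError("which must be 'g1', 'g2' or 'mixture'")
    c1 = coefficients if coefficients is not None else default_g1(dgp)
    c2 = g2 if g2 is not None else default_g2()
    if which == "g1":
        return c1.evaluate(X)
    if which == "g2":
        return c2.evaluate(X)
    w1, w2 = mixture_weights
    return w1 * c1.evaluate(X) + w2 * c2.evaluate(X)


def calibrate_thresholds(
    latent_sampler,
    target_proportions,
    pilot_n: int = 100_000,
    seed=None,
) -> np.ndarray:
    """Thresholds placing a latent variable's mass at target proportions.

    ``latent_sampler(m, rng)`` must return ``m`` draws of the latent value
    whose quantiles become the thresholds: for a proportional-odds response
    that is ``V = L - g(x)`` with ``L`` standard logistic (so that
    ``Y <= r  <=>  V <= gamma_r`` has probability ``expit(gamma_r + g(x))``
    given ``x``); for a binned regression it is the numeric outcome itself.
    Returns ``gamma_1 < ... < gamma_{k-1}`` as the empirical quantiles at the
    cumulative targets, which makes the marginal category distribution
    approximate the target for any predictor distribution.
    """
    targets = np.asarray(target_proportions, dtype=float)
    if targets.ndim != 1 or len(targets) < 2:
        raise ValueError("target_proportions must be a probability vector, k >= 2")
    if np.any(targets <= 0) or abs(targets.sum() - 1.0) > 1e-8:
        raise ValueError("target proportions must be positive and sum to 1")
    if pilot_n < 1000:
        raise ValueError("pilot_n must be at least 1000")
    cum = np.cumsum(targets)[:-1]
    if np.any(np.diff(cum) <= 0):
        raise ValueError("cumulative targets must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pilot = np.asarray(latent_sampler(pilot_n, rng), dtype=float)
    return np.quantile(pilot, cum)


def _latent_sampler(config: DGPConfig):
    """Latent-value sampler matching the DGP's generating mechanism."""

    def g_of(X):
        if config.dgp == 3:
            return linear_predictor(
                X, "mixture", coefficients=config.g1, g2=config.g2,
                mixture_weights=config.mixture_weights,
            )
        return config.g1.evaluate(X)

    if config.dgp == 2:

        def sampler(m, rng):
            X = make_covariates(m, config.dgp, rng)
            return config.g1.evaluate(X) + config.noise_sd * rng.standard_normal(m)

    else:

        def sampler(m, rng):
            X = make_covariates(m, config.dgp, rng)
            return rng.logistic(size=m) - g_of(X)

    return sampler, g_of


def _draw_categories(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Category = 1 + number of thresholds strictly below the latent value."""
    return np.searchsorted(thresholds, latent, side="left").astype(int) + 1


def simulate_ordinal(config: DGPConfig, return_info: bool = False):
    """Simulate a pool dataset from the configured DGP.

    DGPs 1/3/4 draw through the proportional-odds mechanism; DGP 2 draws the
    numeric outcome ``g1(x) + noise`` and bins it with calibrated cut-points.
    """
    rng = np.random.default_rng(config.seed)
    sampler, g_of = _latent_sampler(config)
    cal_rng, pool_rng = rng.spawn(2)
    thresholds = calibrate_thresholds(
        sampler, config.targets, pilot_n=config.pilot_n, seed=cal_rng
    )
    X = make_covariates(config.pool_size, config.dgp, pool_rng)
    if config.dgp == 2:
        latent = config.g1.evaluate(X) + config.noise_sd * pool_rng.standard_normal(
            config.pool_size
        )
    else:
        latent = pool_rng.logistic(size=config.pool_size) - g_of(X)
    y = _draw_categories(latent, thresholds)
    dataset = OrdinalDataset(X, y, config.k)
    if return_info:
        info = {
            "thresholds": thresholds,
            "config": asdict(config),
        }
        return dataset, info
    return dataset


def _stratified_indices(y, k, size, rng, available=None):
    """Draw `size` indices with category proportions matching `y`'s."""
    if available is None:
        available = np.arange(len(y))
    y_avail = y[available]
    counts = np.bincount(y, minlength=k + 1)[1:]
    props = counts / counts.sum()
    alloc = np.floor(props * size).astype(int)
    remainder = props * size - alloc
    short = size - alloc.sum()
    if short > 0:
        alloc[np.argsort(-remainder)[:short]] += 1
    chosen = []
    for r in range(1, k + 1):
        pool_r = available[y_avail == r]
        if len(pool_r) < alloc[r - 1]:
            raise ValueError(
                f"insufficient pool observations in category {r} for stratification"
            )
        chosen.append(rng.choice(pool_r, size=alloc[r - 1], replace=False))
    return np.concatenate(chosen)


def sample_train_test(
    pool: OrdinalDataset,
    n: int,
    stratified_train: bool = True,
    seed=None,
) -> tuple[OrdinalDataset, OrdinalDataset]:
    """Disjoint train (2n/3) and test (n/3) subsamples of the pool.

    The test subsample is always category-stratified to the pool
    proportions; the training subsample is stratified only when requested
    (unstratified training lets the training category distribution drift
    from the population's, the misrepresentation scenario).  Non-multiples
    of 3 round the training share to the nearest integer.
    """
    if pool.n < n:
        raise ValueError("pool size must be at least n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_train = int(round(2 * n / 3))
    n_test = n - n_train
    all_idx = np.arange(pool.n)
    if stratified_train:
        train_idx = _stratified_indices(pool.y, pool.k, n_train, rng)
    else:
        train_idx = rng.choice(all_idx, size=n_train, replace=False)
    remaining = np.setdiff1d(all_idx, train_idx)
    test_idx = _stratified_indices(pool.y, pool.k, n_test, rng, available=remaining)
    return pool.subset(train_idx), pool.subset(test_idx)
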