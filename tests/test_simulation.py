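"""Data-generating processes: covariates, predictors, calibration, sampling."""

import numpy as np
import pytest
from scipy.special import expit

from fabof import (
    DGPConfig,
    calibrate_thresholds,
    default_g1,
    default_g2,
    linear_predictor,
    make_covariates,
    pattern_targets,
    sample_train_test,
    simulate_ordinal,
)
from fabof.simulation import PredictorCoefficients, _draw_categories, _latent_sampler


class TestMakeCovariates:
    @pytest.mark.parametrize("dgp", [1, 2, 3, 4])
    def test_fifteen_columns(self, dgp):
        assert make_covariates(50, dgp, seed=0).shape == (50, 15)

    def test_dgp4_binary_columns(self):
        X = make_covariates(10_000, 4, seed=1)
        for col in (4, 14):
            assert set(np.unique(X[:, col])) <= {0.0, 1.0}
            assert abs(X[:, col].mean() - 0.5) < 0.02

    def test_covariates_uncorrelated(self):
        worst = 0.0
        for seed in range(10):
            X = make_covariates(10_000, 1, seed=seed)
            corr = np.corrcoef(X, rowvar=False)
            worst = max(worst, np.abs(corr - np.eye(15)).max())
        assert worst < 0.05

    def test_dgp4_shares_other_columns_with_dgp1(self):
        """Only columns 5 and 15 (and the X5 effect) differ from DGP 1."""
        a = make_covariates(200, 1, seed=33)
        b = make_covariates(200, 4, seed=33)
        keep = [j for j in range(15) if j not in (4, 14)]
        np.testing.assert_array_equal(a[:, keep], b[:, keep])

    def test_invalid_dgp_rejected(self):
        with pytest.raises(ValueError):
            make_covariates(10, 7)


class TestLinearPredictor:
    def test_origin_evaluates_to_zero(self):
        X = np.zeros((1, 15))
        assert linear_predictor(X, "g1")[0] == pytest.approx(0.0)
        assert linear_predictor(X, "g2")[0] == pytest.approx(0.0)

    def test_mixture_is_weighted_sum(self):
        X = make_covariates(100, 3, seed=2)
        g1 = linear_predictor(X, "g1")
        g2 = linear_predictor(X, "g2")
        np.testing.assert_allclose(
            linear_predictor(X, "mixture"), 0.6 * g1 + 0.4 * g2
        )

    def test_influential_and_noise_covariates(self):
        """X1..X6 enter the default predictors; X7..X15 never do."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 15))
        for which in ("g1", "g2"):
            g0 = linear_predictor(base, which)
            for j in range(6, 15):
                X = base.copy()
                X[:, j] += 10.0
                np.testing.assert_array_equal(linear_predictor(X, which), g0)
            moved = 0
            for j in range(6):
                X = base.copy()
                X[:, j] += 1.0
                moved += int(not np.allclose(linear_predictor(X, which), g0))
            assert moved == 6

    def test_dgp4_doubles_x5_effect(self):
        X = np.zeros((1, 15))
        X[0, 4] = 2.0
        assert linear_predictor(X, "g1", dgp=1)[0] == pytest.approx(1.0)  # .5 * 2
        assert linear_predictor(X, "g1", dgp=4)[0] == pytest.approx(2.0)  # 1 * 2

    def test_out_of_range_term_rejected(self):
        with pytest.raises(ValueError):
            PredictorCoefficients(linear=(0.0,) * 15, quadratic=((15, 1.0),))
        with pytest.raises(ValueError):
            PredictorCoefficients(linear=(0.0,) * 14)


class TestThresholdCalibration:
    def test_thresholds_strictly_increasing(self):
        cfg = DGPConfig(dgp=1, n=300, k=5, pattern="equal", pool_size=300,
                        pilot_n=20_000, seed=3)
        sampler, _ = _latent_sampler(cfg)
        gamma = calibrate_thresholds(sampler, cfg.targets, pilot_n=20_000, seed=1)
        assert np.all(np.diff(gamma) > 0)

    def test_bad_targets_rejected(self):
        def sampler(m, rng):
            return rng.normal(size=m)

        with pytest.raises(ValueError):
            calibrate_thresholds(sampler, [0.5, 0.5, 0.0], seed=0)
        with pytest.raises(ValueError):
            calibrate_thresholds(sampler, [0.7, 0.3], pilot_n=10, seed=0)

    def test_wide_middle_targets(self):
        np.testing.assert_allclose(
            pattern_targets("wide_middle", 5), [0.1, 0.2, 0.4, 0.2, 0.1]
        )
        np.testing.assert_allclose(pattern_targets("equal", 4), [0.25] * 4)
        with pytest.raises(ValueError):
            pattern_targets("bogus", 5)


class TestSimulateOrdinal:
    @pytest.mark.parametrize("dgp", [1, 2, 3, 4])
    def test_labels_in_range(self, dgp):
        cfg = DGPConfig(dgp=dgp, n=200, k=5, pool_size=500, pilot_n=10_000, seed=dgp)
        data = simulate_ordinal(cfg)
        assert data.y.min() >= 1 and data.y.max() <= 5
        assert data.n == 500 and data.p == 15

    def test_seeded_reproducibility(self):
        cfg = dict(dgp=3, n=200, k=4, pool_size=400, pilot_n=10_000, seed=77)
        a = simulate_ordinal(DGPConfig(**cfg))
        b = simulate_ordinal(DGPConfig(**cfg))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_dgp2_zero_noise_is_deterministic_binning(self):
        """With the regression noise forced to zero the response is a
        monotone binning of g1(x)."""
        cfg = DGPConfig(dgp=2, n=200, k=5, pool_size=1000, pilot_n=10_000,
                        noise_sd=0.0, seed=11)
        data, info = simulate_ordinal(cfg, return_info=True)
        g = cfg.g1.evaluate(data.X)
        expected = _draw_categories(g, info["thresholds"])
        np.testing.assert_array_equal(data.y, expected)
        order = np.argsort(g)
        assert np.all(np.diff(data.y[order]) >= 0)

    def test_wide_middle_concentrates_central_mass(self):
        cfg = DGPConfig(dgp=1, n=500, k=5, pattern="wide_middle",
                        pool_size=10_000, pilot_n=50_000, seed=13)
        data = simulate_ordinal(cfg)
        freq = np.bincount(data.y, minlength=6)[1:] / data.n
        assert freq[1:4].sum() > freq[0] + freq[4]

    def test_conditional_probabilities_match_closed_form(self):
        """At a fixed covariate row the simulated cumulative frequencies of
        {Y <= r} match expit(gamma_r + g(x))."""
        cfg = DGPConfig(dgp=1, n=300, k=5, pool_size=300, pilot_n=100_000, seed=19)
        _, info = simulate_ordinal(cfg, return_info=True)
        gamma = info["thresholds"]
        x = make_covariates(1, 1, seed=4)
        g = cfg.g1.evaluate(x)[0]
        rng = np.random.default_rng(99)
        V = rng.logistic(size=200_000) - g
        y = _draw_categories(V, gamma)
        for r in range(1, 5):
            emp = (y <= r).mean()
            assert emp == pytest.approx(expit(gamma[r - 1] + g), abs=0.005)


class TestSampleTrainTest:
    def test_two_thirds_split_arithmetic(self, small_pool):
        train, test = sample_train_test(small_pool, 300, seed=0)
        assert (train.n, test.n) == (200, 100)

    def test_stratified_train_matches_pool_proportions(self, small_pool):
        train, _ = sample_train_test(small_pool, 300, stratified_train=True, seed=1)
        pool_p = np.bincount(small_pool.y, minlength=6)[1:] / small_pool.n
        counts = np.bincount(train.y, minlength=6)[1:]
        assert np.all(np.abs(counts - 200 * pool_p) <= 1)

    def test_train_test_disjoint(self):
        cfg = DGPConfig(dgp=1, n=90, k=3, pool_size=120, pilot_n=10_000, seed=8)
        pool = simulate_ordinal(cfg)
        # tag rows by a unique covariate value to detect overlap
        pool.X[:, 0] = np.arange(pool.n)
        train, test = sample_train_test(pool, 90, seed=2)
        assert not set(train.X[:, 0]) & set(test.X[:, 0])

    def test_insufficient_pool_rejected(self, small_pool):
        with pytest.raises(ValueError):
            sample_train_test(small_pool, small_pool.n + 1)


def test_default_coefficient_sets_satisfy_structural_constraints():
    g1, g2 = default_g1(), default_g2()
    assert g1.linear[4] == 0.5 and default_g1(4).linear[4] == 1.0
    assert any(idx <= 5 for idx, _ in g1.quadratic)
    assert any(idx <= 5 for idx, _ in g1.sine)
    assert all(c == 0 for c in g1.linear[6:]) and all(c == 0 for c in g2.linear[6:])
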