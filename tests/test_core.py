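"""Score/border partition model and the TFAA/AFTA prediction schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fabof import (
    OrdinalDataset,
    ScorePartition,
    TreeScoreMatrix,
    afta_predict,
    assign_category,
    midpoint_scores,
    tfaa_predict,
)


def mode_lowest_tie(votes, k):
    """Brute-force modal category with ties broken toward the lowest."""
    best, best_count = None, -1
    for cat in range(1, k + 1):
        c = sum(1 for v in votes if v == cat)
        if c > best_count:
            best, best_count = cat, c
    return best


class TestMidpointScores:
    @pytest.mark.parametrize(
        "borders, expected",
        [
            ([0, 0.2, 0.4, 0.6, 0.8, 1], [0.1, 0.3, 0.5, 0.7, 0.9]),
            ([0, 1], [0.5]),
            ([0, 0.5, 1], [0.25, 0.75]),
        ],
    )
    def test_equal_width_partitions(self, borders, expected):
        np.testing.assert_allclose(midpoint_scores(borders), expected)

    def test_non_monotone_borders_rejected(self):
        with pytest.raises(ValueError, match="invalid partition"):
            midpoint_scores([0, 0.5, 0.4, 1])
        with pytest.raises(ValueError):
            midpoint_scores([0, 0.5, 0.5, 1])

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=8, unique=True)
    )
    @settings(derandomize=True, max_examples=50)
    def test_midpoints_lie_inside_their_interval(self, raw):
        borders = np.sort(np.asarray(raw))
        s = midpoint_scores(borders)
        assert np.all(borders[:-1] <= s) and np.all(s < borders[1:])


class TestAssignCategory:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.15, 1), (1.0, 5), (0.2, 2), (-3.0, 1), (7.0, 5), (0.79999, 4), (0.8, 5)],
    )
    def test_half_open_intervals_with_clipping(self, value, expected):
        assert assign_category(value, [0, 0.2, 0.4, 0.6, 0.8, 1]) == expected

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            assign_category(np.nan, [0, 1])
        with pytest.raises(ValueError):
            assign_category(np.inf, [0, 0.5, 1])

    def test_duplicated_interior_border_skips_empty_interval(self):
        # [b2, b3) is empty, so category 2 is unreachable
        borders = [0, 0.5, 0.5, 1]
        values = np.array([0.2, 0.5, 0.7, 0.49])
        np.testing.assert_array_equal(assign_category(values, borders), [1, 3, 3, 1])

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=7, unique=True),
        st.floats(-6, 6, allow_nan=False),
        st.floats(0, 3, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=80)
    def test_monotone_in_value(self, raw, v, delta):
        borders = np.sort(np.asarray(raw))
        assert assign_category(v + delta, borders) >= assign_category(v, borders)


class TestPredictionSchemes:
    borders = [0.5, 1.5, 2.5, 3.5]

    def test_tfaa_majority_vote(self):
        assert tfaa_predict([[1.4, 2.6, 2.7]], self.borders) == [3]

    def test_tfaa_tie_breaks_to_lowest_category(self):
        assert tfaa_predict([[1.2, 2.8]], self.borders) == [1]

    def test_afta_averages_before_transforming(self):
        # mean 2.2333 -> category 2, separating AFTA from TFAA on this input
        assert afta_predict([[1.4, 2.6, 2.7]], self.borders) == [2]
        assert tfaa_predict([[1.4, 2.6, 2.7]], self.borders) == [3]

    def test_constant_tree_scores(self):
        values = np.full((4, 6), 2.9)
        np.testing.assert_array_equal(afta_predict(values, self.borders), [3, 3, 3, 3])

    def test_empty_tree_matrix_rejected(self):
        with pytest.raises(ValueError):
            tfaa_predict(np.empty((3, 0)), self.borders)
        with pytest.raises(ValueError):
            afta_predict(np.empty((0, 0)), self.borders)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_single_tree_makes_schemes_identical(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 4, size=(10, 1))
        np.testing.assert_array_equal(
            tfaa_predict(values, self.borders), afta_predict(values, self.borders)
        )

    @given(st.integers(0, 2**31 - 1), st.integers(1, 15), st.integers(1, 20))
    @settings(derandomize=True, max_examples=40)
    def test_tfaa_matches_vote_counting_oracle(self, seed, n_trees, n_obs):
        rng = np.random.default_rng(seed)
        borders = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        values = rng.uniform(0, 6.5, size=(n_obs, n_trees))
        got = tfaa_predict(values, borders)
        votes = assign_category(values, borders)
        expected = [mode_lowest_tie(row, 5) for row in votes]
        np.testing.assert_array_equal(got, expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_predictions_stay_in_category_range(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 10, size=(25, 7))
        for preds in (tfaa_predict(values, self.borders), afta_predict(values, self.borders)):
            assert preds.min() >= 1 and preds.max() <= 3


class TestDomainTypes:
    def test_dataset_validation(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            OrdinalDataset(X, [1, 2, 3, 9], 3)
        with pytest.raises(ValueError):
            OrdinalDataset(X, [1, 2, 0, 1], 3)
        with pytest.raises(ValueError):
            OrdinalDataset(X, [1, 2, 2, 1], 1)
        with pytest.raises(ValueError):
            OrdinalDataset(np.array([[1.0, np.nan]]), [1], 2)
        ds = OrdinalDataset(X, [1, 2, 3, 1], 3)
        assert ds.covariate_names == ["X1", "X2"]

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            ScorePartition([0, 1], [0.5, 0.6])
        with pytest.raises(ValueError):
            ScorePartition([1, 0.5, 2], [0.7, 1.2])
        part = ScorePartition.from_borders([0, 0.2, 0.4, 0.6, 0.8, 1])
        np.testing.assert_allclose(part.scores, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert part.k == 5

    def test_tree_matrix_validation(self):
        with pytest.raises(ValueError):
            TreeScoreMatrix(np.array([[np.inf, 1.0]]))
        with pytest.raises(ValueError):
            TreeScoreMatrix(np.empty((2, 0)))
        assert TreeScoreMatrix(np.ones((3, 2))).n_trees == 2
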