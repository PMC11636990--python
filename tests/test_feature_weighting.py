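"""Chi-squared and Relief scoring plus IEMOA weight optimization."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from hydrosoil.data import LabeledTable, SyntheticConfig, generate_synthetic_dataset
from hydrosoil.feature_weighting import (
    WeightVector,
    apply_weights,
    chi_squared_feature_score,
    make_anchors,
    optimize_feature_weights,
    relief_scores,
    weighting_objective,
)
from hydrosoil.iemoa import IEMOAConfig


class TestChiSquared:
    def test_independent_counts_score_zero(self):
        values = np.repeat([0.0, 0.0, 1.0, 1.0], 15)
        labels = np.repeat([0, 1, 0, 1], 15)
        assert chi_squared_feature_score(values, labels, [0, 0.5, 1]) == pytest.approx(0.0)

    def test_two_bin_two_class_hand_value(self):
        values = np.repeat([0.0, 0.0, 1.0, 1.0], [10, 20, 20, 10])
        labels = np.repeat([0, 1, 0, 1], [10, 20, 20, 10])
        score = chi_squared_feature_score(values, labels, [0, 0.5, 1])
        assert score == pytest.approx(4 * 25 / 15, abs=1e-9)  # 6.6667

    def test_perfect_association_equals_n(self):
        values = np.repeat([0.0, 1.0], 10)
        labels = np.repeat([0, 1], 10)
        assert chi_squared_feature_score(values, labels, [0, 0.5, 1]) == pytest.approx(20.0)

    def test_single_class_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            score = chi_squared_feature_score(np.arange(5.0), np.zeros(5), [0, 2, 4])
        assert score == 0.0

    def test_scipy_oracle_equivalence(self, rng):
        """Random configurations agree with scipy's uncorrected chi-squared."""
        for _ in range(200):
            n = int(rng.integers(20, 60))
            values = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 4), size=n)
            if np.unique(labels).size < 2:
                continue
            edges = np.quantile(values, np.linspace(0, 1, rng.integers(3, 6)))
            edges = np.unique(edges)
            if edges.size < 3:
                continue
            ours = chi_squared_feature_score(values, labels, edges)
            bins = np.clip(
                np.searchsorted(edges, values, side="right") - 1, 0, edges.size - 2
            )
            table = np.zeros((edges.size - 1, np.max(labels) + 1))
            np.add.at(table, (bins, labels), 1)
            table = table[table.sum(1) > 0][:, table.sum(0) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                continue
            expected = chi2_contingency(table, correction=False).statistic
            assert ours == pytest.approx(expected, abs=1e-9)


class TestRelief:
    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        ranges = X.max(0) - X.min(0)
        scores = relief_scores(X, labels, ranges)
        assert scores[0] == 0.0

    def test_label_copy_feature_scores_one(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        labels = np.array([0, 0, 1, 1])
        assert relief_scores(X, labels, np.array([1.0]))[0] == pytest.approx(1.0)

    def test_noise_feature_null_mean(self):
        """Pure-noise scores average to ~0 over Monte-Carlo datasets."""
        means = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 1))
            labels = rng.integers(0, 2, size=200)
            ranges = X.max(0) - X.min(0)
            means.append(relief_scores(X, labels, ranges)[0])
        assert abs(np.mean(means)) < 0.05

    def test_boundedness(self, rng):
        for _ in range(20):
            X = rng.normal(size=(30, 3))
            labels = rng.integers(0, 2, size=30)
            ranges = X.max(0) - X.min(0)
            scores = relief_scores(X, labels, ranges)
            assert np.all(scores >= -1.0 - 1e-12) and np.all(scores <= 1.0 + 1e-12)

    def test_permutation_destroys_signal(self):
        X = np.repeat([0.0, 1.0], 20)[:, None]
        labels = np.repeat([0, 1], 20)
        ranges = np.array([1.0])
        assert relief_scores(X, labels, ranges)[0] == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        perm_scores = [
            relief_scores(X, rng.permutation(labels), ranges)[0] for _ in range(50)
        ]
        assert abs(np.mean(perm_scores)) < 0.05

    def test_singleton_class_pivot_skipped(self):
        X = np.array([[0.0], [0.1], [1.0]])
        labels = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="only member"):
            scores = relief_scores(X, labels, np.array([1.0]))
        assert np.isfinite(scores).all()


class TestWeightingObjective:
    def test_zero_variance_dataset_scores_zero(self):
        t = LabeledTable(np.ones((8, 2)), ["a", "b"], np.repeat(["x", "y"], 4))
        anchors = make_anchors(t)
        w = WeightVector(np.array([0.5, 0.5]))
        assert weighting_objective(w, t, anchors) == pytest.approx(0.0)

    def test_pure_function_of_inputs(self, small_table):
        anchors = make_anchors(small_table)
        w = WeightVector(np.array([0.3, 0.7]))
        a = weighting_objective(w, small_table, anchors)
        b = weighting_objective(w, small_table, anchors)
        assert a == b

    def test_raising_informative_weight_helps_relief(self):
        # feature 0 copies the label; feature 1 is fixed noise
        X = np.array([[0.0, 0.3], [0.0, 0.9], [1.0, 0.1], [1.0, 0.7]])
        t = LabeledTable(X, ["sig", "noise"], np.array([0, 0, 1, 1]))
        anchors = make_anchors(t)
        low = weighting_objective(WeightVector(np.array([0.01, 0.5])), t, anchors)
        high = weighting_objective(WeightVector(np.array([0.99, 0.5])), t, anchors)
        assert high >= low

    def test_anchor_mismatch_rejected(self, small_table):
        anchors = make_anchors(small_table)
        with pytest.raises(ValueError):
            weighting_objective(WeightVector(np.array([0.5])), small_table, anchors)


class TestOptimizeWeights:
    def test_weights_within_bounds_and_beat_random(self):
        t = generate_synthetic_dataset(
            SyntheticConfig(n_samples=80, n_compounds=2, n_noise_features=2,
                            effect_size=3.0, seed=0)
        )
        cfg = IEMOAConfig(population_size=6, max_iterations=10, seed=0)
        anchors = make_anchors(t)
        weights, result = optimize_feature_weights(t, cfg, anchors)
        assert np.all(weights.weights >= 0.01) and np.all(weights.weights <= 0.99)
        rng = np.random.default_rng(0)
        random_objs = [
            weighting_objective(
                WeightVector(0.01 + 0.98 * rng.random(t.n_features)), t, anchors
            )
            for _ in range(20)
        ]
        assert result.best_value >= np.median(random_objs)

    def test_deterministic_under_seed(self):
        t = generate_synthetic_dataset(
            SyntheticConfig(n_samples=60, n_compounds=2, effect_size=2.0, seed=1)
        )
        cfg = IEMOAConfig(population_size=4, max_iterations=5, seed=3)
        w1, r1 = optimize_feature_weights(t, cfg)
        w2, r2 = optimize_feature_weights(t, cfg)
        assert np.array_equal(w1.weights, w2.weights)
        assert np.array_equal(r1.trace, r2.trace)


class TestApplyWeights:
    def test_uniform_weight_scales_matrix(self, small_table):
        w = WeightVector(np.full(2, 0.25))
        out = apply_weights(small_table, w)
        assert np.allclose(out.features, 0.25 * small_table.features)
        assert np.array_equal(out.labels, small_table.labels)

    def test_inverse_recovers_input(self, small_table):
        w = WeightVector(np.array([0.2, 0.8]))
        out = apply_weights(small_table, w)
        assert np.allclose(out.features / w.weights, small_table.features, atol=1e-12)

    def test_length_mismatch(self, small_table):
        with pytest.raises(ValueError):
            apply_weights(small_table, WeightVector(np.array([0.5])))
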