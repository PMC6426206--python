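"""NCA probabilities, objective, gradient, fitting and selection."""

import numpy as np
import pytest
from scipy.stats import binomtest

import thermoface as tf
from oracles import nca_pij_loops


def random_problem(seed, n=8, d=4, classes=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = rng.integers(0, classes, size=n)
    while np.unique(y).size < 2:
        y = rng.integers(0, classes, size=n)
    w = rng.uniform(0.2, 2.0, size=d)
    return X, y, w


class TestProbabilities:
    def test_two_samples_force_assignment(self):
        X = np.array([[0.0, 1.0], [3.0, -2.0]])
        P = tf.nca_probabilities(X, np.ones(2), sigma=1.0)
        np.testing.assert_allclose(P, [[0, 1], [1, 0]], atol=1e-15)

    def test_large_sigma_gives_uniform_neighbours(self):
        X, y, w = random_problem(0, n=6)
        P = tf.nca_probabilities(X, w, sigma=1e12)
        off_diag = P[~np.eye(6, dtype=bool)]
        np.testing.assert_allclose(off_diag, 1 / 5, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        X, y, w = random_problem(seed, n=5, d=3)
        P = tf.nca_probabilities(X, w, sigma=0.8)
        np.testing.assert_allclose(P, nca_pij_loops(X, w, 0.8), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one_and_diag_zero(self, seed):
        X, y, w = random_problem(seed, n=9, d=5)
        P = tf.nca_probabilities(X, w, sigma=0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(np.diag(P), 0.0)

    def test_identical_samples_give_uniform_rows(self):
        X = np.ones((4, 3))
        P = tf.nca_probabilities(X, np.ones(3), sigma=1.0)
        np.testing.assert_allclose(P[~np.eye(4, dtype=bool)], 1 / 3)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            tf.nca_probabilities(np.eye(3), np.ones(3), sigma=0.0)


class TestObjective:
    def test_zero_weights_closed_form(self):
        # w = 0: uniform p_ij, so p_i = (|class_i| - 1) / (N - 1)
        X, _, _ = random_problem(1, n=10, d=4)
        y = np.array([0] * 6 + [1] * 4)
        expected = 6 * (5 / 9) + 4 * (3 / 9)
        assert tf.nca_objective(X, y, np.zeros(4)) == pytest.approx(expected)

    def test_separated_classes_objective_approaches_n(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        y = np.array([0, 0, 1, 1])
        obj = tf.nca_objective(X, y, np.array([30.0]), sigma=1.0, lam=0.0)
        assert obj > 3.99  # each p_i -> 1, sum -> N = 4

    def test_penalty_strictly_reduces_objective(self):
        X, y, w = random_problem(2)
        assert (tf.nca_objective(X, y, w, lam=0.5)
                < tf.nca_objective(X, y, w, lam=0.0))

    def test_label_length_mismatch_rejected(self):
        X, y, w = random_problem(3)
        with pytest.raises(ValueError, match="label"):
            tf.nca_objective(X, y[:-1], w)


class TestGradient:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_central_finite_differences(self, seed):
        X, y, w = random_problem(seed, n=10, d=6, classes=3)
        lam, sigma = 0.3, 1.2
        g = tf.nca_gradient(X, y, w, sigma, lam)
        num = np.zeros_like(w)
        for l in range(w.size):
            e = np.zeros_like(w)
            e[l] = 1e-6
            num[l] = (tf.nca_objective(X, y, w + e, sigma, lam)
                      - tf.nca_objective(X, y, w - e, sigma, lam)) / 2e-6
        np.testing.assert_allclose(g, num, rtol=1e-6, atol=1e-9)

    def test_zero_weights_are_stationary(self):
        X, y, _ = random_problem(4)
        np.testing.assert_array_equal(
            tf.nca_gradient(X, y, np.zeros(4), lam=0.0), 0.0)

    def test_large_lambda_penalty_dominates(self):
        X, y, w = random_problem(5)
        lam = 1e6
        np.testing.assert_allclose(tf.nca_gradient(X, y, w, 1.0, lam),
                                   -2 * lam * w, rtol=1e-3)


class TestFit:
    def test_planted_informative_feature_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 10))
            X[:, 3] += np.where(y == 0, -2.5, 2.5)  # 5-sd class separation
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            fit = tf.fit_nca(Z, y, lam=1.0 / n)
            sel = tf.select_features(fit)
            hits += int(np.argmax(fit.w) == 3 and 3 in sel)
        assert hits >= 19  # >= 95% of seeds

    def test_huge_lambda_shrinks_all_weights(self):
        X, y, _ = random_problem(6, n=20, d=5)
        fit = tf.fit_nca(X, y, lam=100.0)
        assert np.all(fit.w < 1e-2)

    def test_objective_trace_non_decreasing(self):
        X, y, _ = random_problem(7, n=30, d=6, classes=3)
        fit = tf.fit_nca(X, y)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs >= -1e-12)

    def test_weight_norm_monotone_in_lambda(self):
        X, y, _ = random_problem(8, n=40, d=6, classes=2)
        norms = []
        for lam in (0.005, 0.02, 0.1, 0.5, 2.0):
            fit = tf.fit_nca(X, y, lam=lam, max_iter=200, tol=1e-9)
            norms.append((fit.w ** 2).sum())
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_deterministic_given_inputs(self):
        X, y, _ = random_problem(9, n=25, d=5)
        a = tf.fit_nca(X, y)
        b = tf.fit_nca(X, y)
        np.testing.assert_array_equal(a.w, b.w)
        assert a.objective_trace == b.objective_trace

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            tf.fit_nca(X, np.zeros(10))

    def test_permuted_labels_select_at_chance_only(self):
        # under label permutation no feature should be selected more
        # often than chance (binomial test per feature, Bonferroni)
        rng = np.random.default_rng(10)
        n, d, runs = 30, 8, 50
        X = rng.normal(size=(n, d))
        y = np.repeat([0, 1], n // 2)
        counts = np.zeros(d)
        for r in range(runs):
            perm = rng.permutation(n)
            fit = tf.fit_nca(X, y[perm], lam=1.0 / n, max_iter=30)
            counts[tf.select_features(fit)] += 1
        p_hat = counts.sum() / (runs * d)
        for c in counts:
            p = binomtest(int(c), runs, p_hat, alternative="greater").pvalue
            assert p > 0.05 / d


class TestSelection:
    def test_relative_threshold_rule(self):
        sel = tf.select_features(np.array([1.0, 0.01, 0.005]), tau=0.1)
        np.testing.assert_array_equal(sel, [0])

    def test_all_equal_weights_select_everything(self):
        sel = tf.select_features(np.ones(7), tau=0.1)
        np.testing.assert_array_equal(sel, np.arange(7))

    def test_never_empty_falls_back_to_argmax(self):
        sel = tf.select_features(np.zeros(5), tau=0.1)
        assert sel.size == 1

    def test_top_n_rule(self):
        sel = tf.select_features(np.array([0.1, 0.9, 0.5, 0.7]), top_n=2)
        np.testing.assert_array_equal(sel, [1, 3])

    def test_frequency_tally_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        names = tf.feature_names()
        runs = [rng.choice(154, size=rng.integers(1, 30), replace=False)
                for _ in range(7)]
        freq = tf.selection_frequency(runs, names=names)
        # counting oracle
        expect = np.zeros(154, dtype=int)
        for run in runs:
            for i in set(run.tolist()):
                expect[i] += 1
        for i, name in enumerate(names):
            roi, fid = name.rsplit("_", 1)
            assert freq.loc[roi, fid] == expect[i]
        assert freq.attrs["n_runs"] == 7
        assert freq.to_numpy().min() >= 0
        assert freq.to_numpy().max() <= 7

    def test_single_and_identical_runs(self):
        names = tf.feature_names()
        one = tf.selection_frequency([[0, 5, 9]], names=names)
        assert set(np.unique(one.to_numpy())) <= {0, 1}
        three = tf.selection_frequency([[0, 5, 9]] * 3, names=names)
        assert set(np.unique(three.to_numpy())) <= {0, 3}
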