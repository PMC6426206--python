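"""Segment-wise CV splits, normalization, LDA and classification metrics."""

import numpy as np
import pandas as pd
import pytest

import thermoface as tf
from oracles import metrics_loops


def labels_for(segment_sizes):
    out = []
    for i, n in enumerate(segment_sizes):
        out += [f"emo{i}"] * n
    return np.array(out, dtype=object)


class TestSegmentSplits:
    def test_261_frame_segment_partitions_into_87s(self):
        splits = tf.make_segment_splits(labels_for([261]), k=3, seed=0)
        sizes = sorted(len(s.val_idx) for s in splits)
        assert sizes == [87, 87, 87]

    def test_validation_chunks_are_contiguous(self):
        splits = tf.make_segment_splits(labels_for([30, 30]), k=3, seed=1)
        for s in splits:
            for seg_start in (0, 30):
                chunk = s.val_idx[(s.val_idx >= seg_start)
                                  & (s.val_idx < seg_start + 30)]
                assert chunk.size > 0
                assert np.array_equal(chunk,
                                      np.arange(chunk[0], chunk[-1] + 1))

    def test_disjoint_and_covering(self):
        labels = labels_for([40, 40, 40, 40, 40])
        splits = tf.make_segment_splits(labels, k=3, seed=2)
        all_val = np.concatenate([s.val_idx for s in splits])
        assert np.array_equal(np.sort(all_val), np.arange(200))
        for s in splits:
            assert np.intersect1d(s.train_idx, s.val_idx).size == 0
            # every emotion present in every training fold
            assert set(labels[s.train_idx]) == set(labels)

    def test_k1_and_short_segments_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            tf.make_segment_splits(labels_for([30]), k=1)
        with pytest.raises(ValueError, match="fewer than k"):
            tf.make_segment_splits(labels_for([30, 2]), k=3)

    def test_seed_determinism_and_variation(self):
        labels = labels_for([30, 30])
        a = tf.make_segment_splits(labels, k=3, seed=5)
        b = tf.make_segment_splits(labels, k=3, seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.val_idx, sb.val_idx)
        c = tf.make_segment_splits(labels, k=3, seed=6)
        assert any(not np.array_equal(sa.val_idx, sc.val_idx)
                   for sa, sc in zip(a, c))


class TestNormalizer:
    def test_train_zscores_match_loop_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(3, 5, size=(20, 4))
        norm = tf.fit_normalizer(X)
        Z = tf.apply_normalizer(X, norm)
        for j in range(4):
            mu = sum(X[:, j]) / 20
            sd = (sum((x - mu) ** 2 for x in X[:, j]) / 19) ** 0.5
            np.testing.assert_allclose(Z[:, j], (X[:, j] - mu) / sd,
                                       atol=1e-12)
        np.testing.assert_allclose(Z.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_guard(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z = tf.apply_normalizer(X, tf.fit_normalizer(X))
        np.testing.assert_array_equal(Z[:, 0], 0.0)

    def test_validation_uses_training_statistics_only(self):
        rng = np.random.default_rng(13)
        Xtr = rng.normal(size=(15, 3))
        Xval = rng.normal(10, 3, size=(6, 3))
        norm = tf.fit_normalizer(Xtr)
        before = (norm.mean.copy(), norm.sd.copy())
        Zval = tf.apply_normalizer(Xval, norm)
        np.testing.assert_array_equal(norm.mean, before[0])
        np.testing.assert_array_equal(norm.sd, before[1])
        assert Zval.mean() > 2  # val not re-centered on itself

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            tf.fit_normalizer(np.empty((1, 3)))


class TestLDA:
    def test_separated_blobs_classified_perfectly(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(8, 1, (50, 2))])
        y = np.repeat(["a", "b"], 50)
        model = tf.lda_fit(X, y)
        Xv = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(8, 1, (30, 2))])
        yv = np.repeat(["a", "b"], 30)
        assert (tf.lda_predict(model, Xv) == yv).mean() == 1.0

    def test_identical_distributions_give_chance_accuracy(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 3))
            y = np.tile(np.arange(4), 50)
            model = tf.lda_fit(X[:100], y[:100])
            accs.append((tf.lda_predict(model, X[100:]) == y[100:]).mean())
        assert abs(np.mean(accs) - 0.25) < 0.05

    def test_1d_boundary_matches_closed_form(self):
        # equal-variance 1-D two-class LDA with uniform priors decides
        # at the midpoint of the class means
        rng = np.random.default_rng(15)
        mu0, mu1 = 0.0, 4.0
        X = np.concatenate([rng.normal(mu0, 1, 200),
                            rng.normal(mu1, 1, 200)])[:, None]
        y = np.repeat([0, 1], 200)
        model = tf.lda_fit(X, y)
        m0, m1 = X[y == 0].mean(), X[y == 1].mean()
        boundary = (m0 + m1) / 2
        grid = np.linspace(mu0 - 2, mu1 + 2, 401)[:, None]
        pred = tf.lda_predict(model, grid)
        expected = (grid[:, 0] > boundary).astype(int)
        mismatch = np.abs(grid[pred != expected, 0] - boundary)
        assert mismatch.size == 0 or mismatch.max() < 1e-6

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            tf.lda_fit(np.zeros((10, 2)), np.zeros(10))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(list("abcde"), 10)
        rep = tf.evaluate(y, y)
        assert rep.accuracy == 1.0 and rep.kappa == 1.0
        assert (rep.per_class.fpr == 0).all()
        assert (rep.per_class.tpr == 1).all()

    def test_all_one_class_on_balanced_truth(self):
        y = np.repeat(list("abcde"), 20)
        pred = np.full(100, "a")
        rep = tf.evaluate(y, pred, labels=list("abcde"))
        assert rep.accuracy == pytest.approx(0.2)
        assert rep.kappa == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("abcde")
        y = rng.choice(labels, 200)
        pred = rng.choice(labels, 200)
        rep = tf.evaluate(y, pred, labels=labels)
        cm, acc, per, kappa = metrics_loops(y, pred, labels)
        np.testing.assert_array_equal(rep.confusion, cm)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.kappa == pytest.approx(kappa)
        for lab in labels:
            for metric in ("accuracy", "tpr", "fpr"):
                assert rep.per_class.loc[lab, metric] == pytest.approx(
                    per[lab][metric], nan_ok=True)

    def test_metric_identities(self):
        rng = np.random.default_rng(16)
        y = rng.choice(list("abc"), 120)
        pred = rng.choice(list("abc"), 120)
        rep = tf.evaluate(y, pred)
        weights = rep.confusion.sum(axis=1) / rep.confusion.sum()
        recall_mean = float((weights * rep.per_class.tpr).sum())
        assert rep.accuracy == pytest.approx(recall_mean)
        assert rep.kappa <= rep.accuracy + 1e-12
        assert -1.0 <= rep.kappa <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tf.evaluate([], [])


class TestPipeline:
    def test_high_snr_session_recovered(self, noisy_features):
        res = tf.run_classification_pipeline(noisy_features, k=3, seed=0)
        assert res.report.accuracy >= 0.9
        assert res.report.kappa >= 0.85
        assert len(res.fold_reports) == 3
        # baseline excluded from the 5-class problem
        assert set(res.report.labels) == set(tf.DEFAULT_EMOTIONS)

    def test_fold_determinism(self, noisy_features):
        a = tf.run_classification_pipeline(noisy_features, k=3, seed=3)
        b = tf.run_classification_pipeline(noisy_features, k=3, seed=3)
        assert a.report.accuracy == b.report.accuracy
        np.testing.assert_array_equal(a.report.confusion, b.report.confusion)
        for sa, sb in zip(a.fold_selected, b.fold_selected):
            np.testing.assert_array_equal(sa, sb)

    def test_no_leakage_from_validation_rows(self, noisy_features):
        # perturbing fold-0 validation rows must not change the objects
        # fitted on fold-0 training rows
        base = tf.run_classification_pipeline(noisy_features, k=3, seed=1)
        rows = noisy_features[noisy_features.label != "baseline"]
        corrupted = noisy_features.copy()
        val0 = rows.index[base.splits[0].val_idx]
        corrupted.loc[val0, tf.feature_names()] *= 100.0
        alt = tf.run_classification_pipeline(corrupted, k=3, seed=1)
        np.testing.assert_array_equal(base.fold_selected[0],
                                      alt.fold_selected[0])
        np.testing.assert_allclose(base.fold_weights[0].w,
                                   alt.fold_weights[0].w, atol=1e-12)

    def test_zero_effect_session_near_chance(self):
        cfg = tf.SessionConfig(noise_sd=2.0, seed=21).scaled(1 / 4)
        sess = tf.generate_session(cfg)  # no effects
        feats = tf.segment_features(sess.frames, sess.roi_set, sess.segments)
        res = tf.run_classification_pipeline(feats, k=3, seed=0)
        assert abs(res.report.accuracy - 0.2) < 0.12
        assert abs(res.report.kappa) < 0.15

    def test_selection_frequency_counts_bounded_by_folds(self, noisy_features):
        res = tf.run_classification_pipeline(noisy_features, k=3, seed=2)
        assert res.frequency.to_numpy().max() <= 3
        assert res.frequency.attrs["n_runs"] == 3
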