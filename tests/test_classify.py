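"""Normalization, PCA, ELM, LSTM, LOSO CV and the statistics harness."""

import numpy as np
import pytest

from driversense.classify import (CVResult, ELMClassifier, LSTMClassifier,
                                  SymmetricMinMaxScaler, anova_oneway, auc,
                                  loso_cv, normalize_features, paired_ttest,
                                  pca_reduce, tribas)


def brute_force_auc(scores, y) -> float:
    """Independent oracle: exhaustive concordant-pair counting, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _separable_toy(rng, n=40, d=8, margin=3.0):
    X = np.vstack([rng.normal(-margin, 1.0, (n // 2, d)),
                   rng.normal(margin, 1.0, (n // 2, d))]) / (margin + 3)
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return X, y


class TestScaler:
    def test_column_maps_to_symmetric_unit_interval(self):
        out = normalize_features(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(out.ravel(), [-1, 0, 1])

    def test_constant_column_maps_to_zero(self):
        out = normalize_features(np.array([[3.0, 1.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_train_only_scope_does_not_clip(self):
        scaler = SymmetricMinMaxScaler().fit(np.array([[0.0], [10.0]]))
        out = scaler.transform(np.array([[15.0]]))
        assert out[0, 0] == pytest.approx(2.0)     # beyond +1, by design

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(np.empty((0, 3)))


class TestPCA:
    def test_full_rank_identity_reconstruction(self, rng):
        X = rng.standard_normal((30, 5))
        Z, basis = pca_reduce(X, 5)
        np.testing.assert_allclose(basis.inverse_transform(Z), X, atol=1e-10)

    def test_one_axis_data_explains_everything(self):
        t = np.linspace(-1, 1, 50)
        X = np.column_stack([t, 2 * t])
        _, basis = pca_reduce(X, 1)
        assert basis.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        """Component variances agree with an independent eigendecomposition
        of the sample covariance matrix."""
        X = rng.standard_normal((200, 10)) @ rng.standard_normal((10, 10))
        _, basis = pca_reduce(X, 10)
        eigs = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(basis.explained_variance_, eigs, atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k="):
            pca_reduce(rng.standard_normal((5, 3)), 5)


class TestELM:
    def test_tribas_activation_values(self):
        np.testing.assert_array_equal(
            tribas(np.array([0.0, 1.0, -1.0, 2.0, 0.5])),
            [1.0, 0.0, 0.0, 0.0, 0.5])

    def test_overparameterized_interpolation(self, rng):
        X, y = _separable_toy(rng)
        clf = ELMClassifier(n_hidden=170, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_deterministic_given_seed(self, rng):
        X, y = _separable_toy(rng)
        w1 = ELMClassifier(random_state=3).fit(X, y).output_weights_
        w2 = ELMClassifier(random_state=3).fit(X, y).output_weights_
        np.testing.assert_array_equal(w1, w2)

    def test_score_zero_breaks_tie_to_positive_class(self, rng):
        X, y = _separable_toy(rng)
        clf = ELMClassifier(random_state=0).fit(X, y)
        clf.output_weights_ = np.zeros_like(clf.output_weights_)
        assert np.all(clf.predict(X) == 1)

    def test_feature_count_mismatch_rejected(self, rng):
        X, y = _separable_toy(rng, d=8)
        clf = ELMClassifier(random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            clf.predict(rng.standard_normal((3, 5)))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            ELMClassifier().fit(rng.standard_normal((10, 3)), np.ones(10))

    def test_training_accuracy_nondecreasing_in_width(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.where(np.sin(3 * X[:, 0]) + X[:, 1] > 0, 1, -1)
        accs = [np.mean(ELMClassifier(n_hidden=h, random_state=1)
                        .fit(X, y).predict(X) == y)
                for h in (10, 50, 170)]
        assert accs[0] <= accs[1] + 1e-9 and accs[1] <= accs[2] + 1e-9

    def test_row_permutation_permutes_predictions(self, rng):
        X, y = _separable_toy(rng)
        clf = ELMClassifier(random_state=0).fit(X, y)
        perm = rng.permutation(len(X))
        np.testing.assert_array_equal(clf.predict(X[perm]),
                                      clf.predict(X)[perm])


class TestLSTM:
    def _sequences(self, rng, n=12, T=15, d=6):
        mu = np.zeros((T, d))
        mu[:, 0] = 1.0
        X = np.concatenate([rng.normal(0, 0.3, (n // 2, T, d)) - mu,
                            rng.normal(0, 0.3, (n // 2, T, d)) + mu])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_overfits_separated_sequences(self, rng):
        X, y = self._sequences(rng)
        clf = LSTMClassifier(layer_sizes=(24, 12), epochs=60,
                             expected_input_dim=None, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).all()
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]

    def test_deterministic_given_seed(self, rng):
        X, y = self._sequences(rng, n=8, T=8, d=4)
        kw = dict(layer_sizes=(10, 6), epochs=5, expected_input_dim=None,
                  random_state=2)
        a = LSTMClassifier(**kw).fit(X, y)
        b = LSTMClassifier(**kw).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_
        np.testing.assert_array_equal(a.w_out_, b.w_out_)

    def test_ragged_sequences_rejected_with_rationale(self, rng):
        seqs = [rng.standard_normal((10, 4)), rng.standard_normal((12, 4))]
        with pytest.raises(ValueError, match="fixed duration"):
            LSTMClassifier(expected_input_dim=None).fit(seqs, [0, 1])

    def test_default_expects_width_60(self, rng):
        X, y = self._sequences(rng, n=6, T=5, d=10)
        with pytest.raises(ValueError, match="60"):
            LSTMClassifier().fit(X, y)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [-1, -1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [-1, 1] * 3) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            y = np.concatenate([np.ones(2), -np.ones(2),
                                rng.choice([-1, 1], n)])
            s = np.round(rng.standard_normal(n + 4), 1)   # force some ties
            assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestStatistics:
    def test_identical_vectors_t_zero(self):
        a = [1.0, 2.0, 3.0]
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p = paired_ttest(a, a)
        assert t == 0.0 and p == 1.0

    def test_textbook_paired_sample(self):
        # classic before/after sample; closed form t = mean(d)/(sd/sqrt(n))
        before = np.array([120., 122., 143., 100., 109.])
        after = np.array([122., 120., 141., 109., 109.])
        d = before - after
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_ttest(before, after)
        assert t == pytest.approx(expected_t, abs=1e-6)
        assert 0 < p < 1

    def test_anova_null_f_near_one_on_average(self):
        """Under equal means/variances E[F] = dfw/(dfw-2) ~ 1; the mean over
        replicates stays within 3 sigma of it."""
        rng = np.random.default_rng(0)
        fs = []
        for _ in range(500):
            groups = [rng.standard_normal(20) for _ in range(4)]
            fs.append(anova_oneway(*groups)[0])
        dfw = 4 * 20 - 4
        expected = dfw / (dfw - 2)
        # var of F(3, 76) mean over 500 reps
        var_f = (2 * expected ** 2 * (3 + dfw - 2)) / (3 * (dfw - 4))
        assert abs(np.mean(fs) - expected) < 3 * np.sqrt(var_f / 500)

    def test_anova_needs_two_groups(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0])


class TestLosoCV:
    def _dataset(self, rng, n_subjects=4, trials=10, effect=2.0, d=6):
        X, y, subs = [], [], []
        for s in range(n_subjects):
            for t in range(trials):
                label = 1 if t % 2 == 0 else -1
                X.append(rng.standard_normal(d) + effect * label)
                y.append(label)
                subs.append(f"S{s}")
        return np.array(X), np.array(y), np.array(subs)

    def test_fold_count_equals_subject_count(self, rng):
        X, y, subs = self._dataset(rng, n_subjects=2)
        res = loso_cv(X, y, subs, pca_k=3, seed=0)
        assert len(res.per_subject_accuracy) == 2

    def test_strong_effect_recovered(self, rng):
        X, y, subs = self._dataset(rng, effect=2.0)
        res = loso_cv(X, y, subs, pca_k=3, seed=0)
        assert res.mean_accuracy > 90.0
        assert res.mean_auc > 0.9

    def test_random_labels_near_chance(self, rng):
        X, y, subs = self._dataset(rng, n_subjects=6, trials=20, effect=0.0)
        y = rng.choice([-1, 1], len(y))
        res = loso_cv(X, y, subs, pca_k=3, seed=0)
        n = len(y)
        band = 3 * np.sqrt(0.25 / n) * 100
        assert abs(res.mean_accuracy - 50.0) < max(band, 15.0)

    def test_trial_order_invariance(self, rng):
        X, y, subs = self._dataset(rng)
        res1 = loso_cv(X, y, subs, pca_k=3, seed=0)
        perm = rng.permutation(len(y))
        res2 = loso_cv(X[perm], y[perm], subs[perm], pca_k=3, seed=0)
        np.testing.assert_allclose(sorted(res1.per_subject_accuracy),
                                   sorted(res2.per_subject_accuracy))

    def test_single_class_test_fold_auc_undefined(self, rng):
        X, y, subs = self._dataset(rng, n_subjects=3)
        y[subs == "S0"] = 1                       # held-out fold single-class
        res = loso_cv(X, y, subs, pca_k=3, seed=0)
        assert np.isnan(res.per_subject_auc[0])

    def test_summary_recomputable_from_entries(self, rng):
        X, y, subs = self._dataset(rng)
        res = loso_cv(X, y, subs, pca_k=3, seed=0)
        assert res.mean_accuracy == pytest.approx(
            np.mean(res.per_subject_accuracy))
        s = res.summary()
        assert set(s) >= {"mean_accuracy_pct", "mean_auc", "p_value_vs_chance"}

    def test_fewer_than_two_subjects_rejected(self, rng):
        X, y, subs = self._dataset(rng, n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            loso_cv(X, y, subs)
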