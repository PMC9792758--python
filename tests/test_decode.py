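"""Decoding: features, classifiers, accuracy maps, region stats, ROC/AUC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vepsource.decode import (AccuracyMap, build_accuracy_map,
                              channel_accuracy, compare_regions,
                              extract_features, roc_over_channels,
                              train_eval_fnn, train_eval_linear)
from vepsource.preprocess import make_split_plan


def _toy_features(n_per_class=40, n_time=100, gap=10.0, sd=0.1, seed=0):
    """Two well-separated Gaussian classes in feature space."""
    rng = np.random.default_rng(seed)
    a = rng.normal(-gap / 2, sd, size=(n_per_class, n_time))
    b = rng.normal(gap / 2, sd, size=(n_per_class, n_time))
    X = np.vstack([a, b])
    labels = np.array(["red"] * n_per_class + ["green"] * n_per_class)
    return X, labels


def _toy_split(n, train_frac=0.8, seed=0):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cut = int(round(train_frac * n))
    return np.sort(perm[:cut]), np.sort(perm[cut:])


class TestFeatures:
    def test_shape_and_content(self, rg_epochs):
        X, labels = extract_features(rg_epochs, 50)
        assert X.shape == (rg_epochs.n_epochs, 100)
        assert labels.shape[0] == X.shape[0]
        i0 = rg_epochs.onset_index
        np.testing.assert_array_equal(X[3], rg_epochs.data[3, 49, i0:i0 + 100])

    def test_empty_window_rejected(self, rg_epochs):
        with pytest.raises(ValueError):
            extract_features(rg_epochs, 50, window_ms=(0.0, 0.0))

    def test_bad_channel_rejected(self, rg_epochs):
        with pytest.raises(ValueError):
            extract_features(rg_epochs, 60)


class TestLinearClassifier:
    def test_separable_toy_is_perfect(self):
        X, labels = _toy_features()
        split = _toy_split(len(labels))
        assert train_eval_linear(X, labels, split) == 1.0

    def test_permuted_labels_are_chance(self):
        """Mean accuracy under label permutation stays in the 99% binomial
        band around 0.5."""
        X, labels = _toy_features(gap=10.0)
        rng = np.random.default_rng(123)
        accs = []
        for rep in range(60):
            perm = rng.permutation(labels)
            split = _toy_split(len(labels), seed=rep)
            accs.append(train_eval_linear(X, perm, split))
        n = 60 * 16    # repeats x test size
        band = 2.576 * np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) < band + 0.02

    def test_single_class_train_rejected(self):
        X, labels = _toy_features(n_per_class=10)
        split = (np.arange(10), np.arange(10, 20))   # train is one class
        with pytest.raises(ValueError):
            train_eval_linear(X, labels, split)


class TestFnnClassifier:
    def test_separable_toy_learned(self):
        X, labels = _toy_features(gap=4.0, sd=0.5)
        split = _toy_split(len(labels))
        assert train_eval_fnn(X, labels, split, seed=1) >= 0.95

    def test_deterministic_under_seed(self):
        X, labels = _toy_features(gap=1.0, sd=1.0, seed=5)
        split = _toy_split(len(labels), seed=2)
        a = train_eval_fnn(X, labels, split, seed=9)
        b = train_eval_fnn(X, labels, split, seed=9)
        assert a == b

    def test_permuted_labels_are_chance(self):
        X, labels = _toy_features(gap=8.0)
        rng = np.random.default_rng(321)
        accs = []
        for rep in range(25):
            perm = rng.permutation(labels)
            split = _toy_split(len(labels), seed=100 + rep)
            accs.append(train_eval_fnn(X, perm, split, seed=rep))
        n = 25 * 16
        band = 2.576 * np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) < band + 0.04


class TestChannelAccuracy:
    def test_single_repeat_equals_direct_call(self, rg_epochs):
        plan = make_split_plan(rg_epochs.n_epochs, rg_epochs.labels,
                               n_repeats=1, seed=3)
        X, labels = extract_features(rg_epochs, 50)
        direct = train_eval_linear(X, labels, plan.splits[0])
        assert channel_accuracy(rg_epochs, 50, "svm", plan) == direct

    def test_unknown_classifier_rejected(self, rg_epochs):
        plan = make_split_plan(rg_epochs.n_epochs, rg_epochs.labels,
                               n_repeats=1, seed=3)
        with pytest.raises(ValueError):
            channel_accuracy(rg_epochs, 50, "forest", plan)

    def test_posterior_signal_beats_frontal_noise(self, rg_epochs):
        plan = make_split_plan(rg_epochs.n_epochs, rg_epochs.labels,
                               n_repeats=8, seed=4)
        posterior = channel_accuracy(rg_epochs, 50, "svm", plan)   # POz
        frontal = channel_accuracy(rg_epochs, 1, "svm", plan)      # Fpz
        assert posterior >= 0.65
        n = 8 * plan.test_size
        band = 2.576 * np.sqrt(0.25 / n)
        assert abs(frontal - 0.5) < band + 0.03


class TestAccuracyMap:
    def test_single_subject_shape(self, rg_epochs):
        amap = build_accuracy_map([rg_epochs], n_repeats=2, seed=0)
        assert amap.accuracy.shape == (1, 59)
        assert np.isfinite(amap.accuracy).all()
        assert ((amap.accuracy >= 0) & (amap.accuracy <= 1)).all()

    def test_entries_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            AccuracyMap(accuracy=np.full((2, 59), 1.5), classifier="svm",
                        pair="RG", n_repeats=1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_accuracy_map([])


class TestCompareRegions:
    def _map(self, post_val, other_val, n_subjects=5):
        acc = np.full((n_subjects, 59), other_val, dtype=float)
        acc[:, 42:] = post_val
        return AccuracyMap(accuracy=acc, classifier="svm", pair="RG",
                           n_repeats=1)

    def test_separated_groups(self, montage):
        res = compare_regions(self._map(0.75, 0.50), montage)
        assert res.median_posterior == 0.75
        assert res.median_other == 0.50
        assert res.p_value < 1e-3
        assert res.n_posterior == 17 * 5 and res.n_other == 42 * 5

    def test_identical_groups_not_significant(self, montage):
        res = compare_regions(self._map(0.6, 0.6), montage)
        assert res.p_value > 0.9


class TestRoc:
    def test_default_positive_state_counts(self):
        rng = np.random.default_rng(8)
        acc = rng.uniform(0.4, 0.9, size=(20, 59))
        amap = AccuracyMap(accuracy=acc, classifier="svm", pair="RG",
                           n_repeats=30)
        res = roc_over_channels(amap)
        assert res.n_positive == 200
        assert res.n_negative == 980
        assert res.n_positive + res.n_negative == 1180

    def test_perfect_separation(self):
        acc = np.full((20, 59), 0.5)
        acc[:, 49:] = 0.9          # codes 50..59
        amap = AccuracyMap(accuracy=acc, classifier="svm", pair="RG",
                           n_repeats=30)
        res = roc_over_channels(amap)
        assert res.auc == 1.0
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_toy_auc_equals_pairwise_concordance(self):
        """Rank AUC must equal brute-force concordance counting with ties."""
        pos = np.array([0.9, 0.7, 0.6, 0.5])
        neg = np.array([0.6, 0.4])
        concordant = 0.0
        for p, q in itertools.product(pos, neg):
            concordant += 1.0 if p > q else (0.5 if p == q else 0.0)
        expected = concordant / (len(pos) * len(neg))
        acc = np.full((1, 59), np.nan)
        acc[0, 49:53] = pos        # four positive codes
        acc[0, :2] = neg
        amap = AccuracyMap(accuracy=acc, classifier="svm", pair="RG",
                           n_repeats=1)
        res = roc_over_channels(amap, positive_codes=tuple(range(50, 54)))
        assert res.auc == pytest.approx(expected, abs=1e-12)
        assert res.n_positive == 4 and res.n_negative == 2

    def test_auc_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(17)
        acc = rng.uniform(0.3, 1.0, size=(6, 59))
        amap = AccuracyMap(accuracy=acc, classifier="svm", pair="GB",
                           n_repeats=1)
        res = roc_over_channels(amap)
        labels = np.tile(np.isin(np.arange(1, 60), range(50, 60)), 6)
        ref = roc_auc_score(labels, acc.ravel())
        assert res.auc == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.sampled_from(["exp", "cube", "affine"]))
    def test_auc_invariant_under_monotone_transforms(self, seed, kind):
        rng = np.random.default_rng(seed)
        acc = rng.uniform(0.2, 1.0, size=(3, 59))
        f = {"exp": np.exp, "cube": lambda v: v ** 3,
             "affine": lambda v: 0.3 * v + 0.1}[kind]
        before = roc_over_channels(
            AccuracyMap(np.clip(acc, 0, 1), "svm", "RG", 1)).auc
        transformed = f(acc)
        transformed = (transformed - transformed.min()) / np.ptp(transformed)
        after = roc_over_channels(
            AccuracyMap(transformed, "svm", "RG", 1)).auc
        assert before == pytest.approx(after, abs=1e-12)

    def test_empty_positive_set_rejected(self):
        amap = AccuracyMap(np.full((2, 59), 0.6), "svm", "RG", 1)
        with pytest.raises(ValueError):
            roc_over_channels(amap, positive_codes=())
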