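"""PCA, fold, classifier-bank and cross-validation tests."""

import numpy as np
import pytest

import eegspect as es
from eegspect.ml import LabeledFeatureSet


def make_set(X, y, subjects=None):
    subjects = subjects if subjects is not None else [f"S{i % 7}" for i in range(len(y))]
    return LabeledFeatureSet(features=X, labels=y, subject_ids=np.array(subjects, dtype=object))


class TestPCA:
    def test_planar_data_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(200, 2))
        X = coords @ basis
        model = es.fit_pca(X, target_variance=0.95)
        assert model.n_components == 2
        # reconstruction from 2 components is essentially exact
        Z = es.pca_transform(model, X)
        back = Z @ model.components + model.mean
        assert np.abs(back - X).max() < 1e-8

    def test_target_one_keeps_full_rank(self, rng):
        X = rng.normal(size=(30, 5))
        model = es.fit_pca(X, target_variance=1.0)
        assert model.n_components == np.linalg.matrix_rank(X - X.mean(axis=0))

    def test_ratios_match_eigenvalue_oracle(self, rng):
        """Explained-variance ratios agree with a direct covariance
        eigen-decomposition."""
        X = rng.normal(size=(100, 50))
        model = es.fit_pca(X, target_variance=1.0)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig / eig.sum()
        np.testing.assert_allclose(model.explained_variance_ratio, expected[: model.n_components], atol=1e-8)

    def test_components_orthonormal_and_ratios_decreasing(self, rng):
        X = rng.normal(size=(60, 20))
        model = es.fit_pca(X, target_variance=0.99)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-10)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_degenerate_training_set_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            es.fit_pca(np.ones((10, 4)))


class TestFolds:
    def test_partition_contract(self, rng):
        fset = make_set(rng.normal(size=(100, 3)), rng.integers(0, 2, 100))
        plan = es.make_folds(fset, k=10, seed=3)
        sizes = [len(plan.test_indices(f)) for f in range(10)]
        assert sizes == [10] * 10
        union = np.concatenate([plan.test_indices(f) for f in range(10)])
        assert sorted(union) == list(range(100))

    def test_stratification(self, rng):
        y = np.array([1] * 70 + [0] * 30)
        fset = make_set(rng.normal(size=(100, 3)), y)
        plan = es.make_folds(fset, k=10, seed=0)
        for f in range(10):
            yt = y[plan.test_indices(f)]
            assert abs((yt == 1).sum() - 7) <= 1
            assert abs((yt == 0).sum() - 3) <= 1

    def test_subject_grouping_keeps_subjects_whole(self, rng):
        subjects = [f"S{i // 10}" for i in range(100)]  # 10 subjects x 10 items
        y = np.array(([1] * 10 + [0] * 10) * 5)
        fset = make_set(rng.normal(size=(100, 3)), y, subjects)
        plan = es.make_folds(fset, k=5, seed=0, grouping="subject")
        for f in range(5):
            test_subj = set(np.array(subjects, dtype=object)[plan.test_indices(f)])
            train_subj = set(np.array(subjects, dtype=object)[plan.train_indices(f)])
            assert not (test_subj & train_subj)

    def test_k_too_large_rejected(self, rng):
        fset = make_set(rng.normal(size=(5, 2)), [0, 1, 0, 1, 0])
        with pytest.raises(ValueError, match="exceeds"):
            es.make_folds(fset, k=10)

    def test_deterministic_given_seed(self, rng):
        fset = make_set(rng.normal(size=(40, 2)), rng.integers(0, 2, 40))
        a = es.make_folds(fset, k=4, seed=9)
        b = es.make_folds(fset, k=4, seed=9)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)


class TestClassifierBank:
    def test_separable_blobs_svm_near_perfect(self, rng):
        n = 200
        X = np.r_[rng.normal(0, 1, size=(n // 2, 5)), rng.normal(5, 1, size=(n // 2, 5))]
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        fset = make_set(X, y)
        rep = es.cross_validate(fset, "svm", k=5, seed=0, pca_target=1.0)
        assert rep.accuracy >= 99.0

    def test_all_names_fit_and_score(self, rng):
        X = np.r_[rng.normal(0, 1, size=(30, 4)), rng.normal(3, 1, size=(30, 4))]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        for name in es.CLASSIFIER_NAMES:
            model = es.train_classifier(name, X, y, seed=0)
            pred, scores = es.predict_with_scores(model, X)
            assert pred.shape == scores.shape == (60,)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            es.train_classifier("svm", X, np.ones(10))

    def test_unknown_name_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown classifier"):
            es.train_classifier("mlp", np.zeros((4, 2)), [0, 1, 0, 1])

    def test_knn_forced_vote(self):
        """k = 9 with nine identical neighbors of one label forces that label."""
        X = np.r_[np.zeros((9, 2)), np.ones((3, 2))]
        y = np.r_[np.ones(9, int), np.zeros(3, int)]
        model = es.train_classifier("knn", X, y)
        assert model.predict([[0.0, 0.0]])[0] == 1


class TestCrossValidate:
    def test_perfect_separation_all_folds(self, rng):
        X = np.r_[rng.normal(0, 0.5, size=(50, 4)), rng.normal(10, 0.5, size=(50, 4))]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        rep = es.cross_validate(make_set(X, y), "lda", k=5, seed=1, pca_target=1.0)
        assert rep.accuracy == 100.0
        assert all(f.f1 == 1.0 for f in rep.per_fold)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 6))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        fset = make_set(X, y)
        a = es.cross_validate(fset, "rf", k=5, seed=4)
        b = es.cross_validate(fset, "rf", k=5, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_leakage_canary(self, rng):
        """A label-revealing feature present only in test items must not
        change CV accuracy: PCA and the classifier are fitted on training
        folds where that column is constant."""
        X = np.r_[rng.normal(0, 1, size=(40, 6)), rng.normal(1.0, 1, size=(40, 6))]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        fset = make_set(X, y)
        plan = es.make_folds(fset, k=5, seed=2)
        base = es.cross_validate(fset, "lda", plan=plan, pca_target=1.0)
        for fold in range(plan.k):
            canary = np.zeros((len(fset), 1))
            te = plan.test_indices(fold)
            canary[te, 0] = y[te] * 100.0
            rigged = LabeledFeatureSet(
                features=np.c_[X, canary], labels=y, subject_ids=fset.subject_ids,
                item_ids=fset.item_ids,
            )
            rep = es.cross_validate(rigged, "lda", plan=plan, pca_target=1.0)
            assert rep.per_fold[fold].accuracy == base.per_fold[fold].accuracy
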