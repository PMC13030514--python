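import numpy as np
import pytest

from weedspec.classifiers import (
    ALGORITHMS,
    FeatureMatrix,
    build_feature_matrix,
    cross_validate,
    fit_simca,
    orthogonal_distances,
    simca_classify,
    train,
)


def separable_two_class(n_per=30, p=10, gap=12.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, p))
    b = rng.normal(gap, 1.0, size=(n_per, p))
    X = np.vstack([a, b])
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    plants = np.array([f"A-{i % 10}" for i in range(n_per)]
                      + [f"B-{i % 10}" for i in range(n_per)])
    return FeatureMatrix(X, labels, plants)


class TestTrain:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_classes_perfect_training_accuracy(self, algorithm):
        fm = separable_two_class()
        clf = train(algorithm, fm, seed=0)
        assert np.mean(clf.predict(fm.X) == fm.labels) == 1.0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_same_seed_identical_predictions(self, algorithm):
        fm = separable_two_class(gap=3.0)
        p1 = train(algorithm, fm, seed=5).predict(fm.X)
        p2 = train(algorithm, fm, seed=5).predict(fm.X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_probabilities_normalised(self, algorithm):
        fm = separable_two_class(gap=3.0)
        proba = train(algorithm, fm, seed=0).predict_proba(fm.X)
        assert proba.shape == (len(fm.X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(proba >= 0)

    def test_single_class_rejected_except_simca(self):
        fm = separable_two_class()
        only_a = fm.subset(np.nonzero(fm.labels == "A")[0])
        for algorithm in ("rf", "svm", "nn", "maxent"):
            with pytest.raises(ValueError, match="2 classes"):
                train(algorithm, only_a, seed=0)
        clf = train("simca", only_a, seed=0)
        assert np.all(clf.predict(fm.X) == "A")

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train("cnn", separable_two_class(), seed=0)

    def test_rf_feature_subsampling_capped_at_available(self):
        fm = separable_two_class(p=5)
        clf = train("rf", fm, seed=0)
        assert clf.model.max_features == 5

    def test_priors_recorded(self):
        fm = separable_two_class()
        clf = train("rf", fm, seed=0)
        assert clf.class_priors == {"A": 0.5, "B": 0.5}


class TestSimca:
    def test_distances_match_bruteforce_oracle(self):
        """Orthogonal distances equal explicit centre-project-residual
        arithmetic on random instances, to 1e-10."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 7))
        y = np.array(["a", "b", "c", "d"] * 10)
        model = fit_simca(X, y, n_components=2)
        Q = rng.normal(size=(15, 7))
        d = orthogonal_distances(model, Q)
        for j, cls in enumerate(model.classes):
            sm = model.submodels[cls]
            for i in range(len(Q)):
                centred = Q[i] - sm.mean
                proj = np.zeros_like(centred)
                for comp in range(sm.loadings.shape[1]):
                    v = sm.loadings[:, comp]
                    proj = proj + (centred @ v) * v
                expected = np.sqrt(np.sum((centred - proj) ** 2))
                assert abs(d[i, j] - expected) < 1e-10

    def test_in_plane_point_zero_distance(self):
        rng = np.random.default_rng(2)
        basis = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        mean_a = np.zeros(6)
        Xa = (rng.normal(size=(30, 2)) @ basis.T) + mean_a
        Xb = rng.normal(50.0, 1.0, size=(30, 6))
        model = fit_simca(np.vstack([Xa, Xb]), np.array(["A"] * 30 + ["B"] * 30))
        x = (np.array([1.5, -2.0]) @ basis.T) + mean_a
        assigned, d = simca_classify(model, x)
        assert assigned == "A"
        assert d[0] == pytest.approx(0.0, abs=1e-10)
        assert d[1] > 1.0

    def test_well_separated_gaussians_fully_recovered(self):
        rng = np.random.default_rng(3)
        Xa = rng.normal(0.0, 1.0, size=(100, 8))
        Xb = rng.normal(10.0, 1.0, size=(100, 8))
        model = fit_simca(np.vstack([Xa, Xb]), np.array(["A"] * 100 + ["B"] * 100))
        test = np.vstack([rng.normal(0, 1, (100, 8)), rng.normal(10, 1, (100, 8))])
        truth = np.array(["A"] * 100 + ["B"] * 100)
        pred = np.array([simca_classify(model, x)[0] for x in test])
        assert np.mean(pred == truth) == 1.0

    def test_dimension_mismatch_rejected(self):
        model = fit_simca(np.zeros((10, 4)) + np.arange(4), np.array(["A", "B"] * 5))
        with pytest.raises(ValueError, match="dimension"):
            orthogonal_distances(model, np.zeros((2, 5)))


class TestCrossValidate:
    def test_grid_of_one_returns_that_point(self):
        fm = separable_two_class()
        hp, scores = cross_validate("rf", fm, grid=[{"n_trees": 20}], folds=5, seed=0)
        assert hp == {"n_trees": 20}
        assert len(scores) == 5

    def test_no_plant_straddles_folds(self):
        from weedspec.classifiers import _grouped_stratified_folds

        fm = separable_two_class()
        folds = _grouped_stratified_folds(fm, 5, seed=0)
        seen = {}
        for f, idx in enumerate(folds):
            for plant in fm.plant_ids[idx]:
                assert seen.setdefault(plant, f) == f

    def test_separable_data_high_cv_accuracy(self):
        fm = separable_two_class()
        _, scores = cross_validate("rf", fm, folds=5, seed=0)
        assert scores.mean() >= 0.95

    def test_too_few_plants_reduces_folds_with_warning(self):
        fm = separable_two_class()
        # collapse species B onto 3 plants
        fm.plant_ids = np.array([p if p.startswith("A") else f"B-{i % 3}"
                                 for i, p in enumerate(fm.plant_ids)])
        with pytest.warns(UserWarning, match="reducing folds"):
            _, scores = cross_validate("rf", fm, folds=5, seed=0)
        assert len(scores) == 3

    def test_fewer_than_two_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            cross_validate("rf", separable_two_class(), folds=1, seed=0)


def test_feature_matrix_from_rois_is_snv_of_means(mini_cohort):
    from weedspec.preprocessing import preprocess

    fm = build_feature_matrix(mini_cohort.rois, window=5)
    expected = preprocess(mini_cohort.rois[0].mean_spectrum, window=5)
    np.testing.assert_allclose(fm.X[0], expected, atol=1e-12)
    assert fm.labels[0] == mini_cohort.rois[0].species


def test_class_imbalance_rf_beats_nn_macro_f1(cohort):
    """On the imbalanced default cohort the forest's macro-F1 exceeds the
    single-hidden-layer network's (robustness to class imbalance)."""
    from weedspec.evaluation_report import evaluate
    from weedspec.roi_sampling import plant_wise_split, split_rois

    plan = plant_wise_split(cohort, 0.7, seed=1)
    train_rois, test_rois = split_rois(cohort, plan)
    fm_train = build_feature_matrix(train_rois)
    fm_test = build_feature_matrix(test_rois)
    macro_f1 = {}
    for algo in ("rf", "nn"):
        rep = evaluate(train(algo, fm_train, seed=1), fm_test)
        macro_f1[algo] = rep.per_class["f1"].mean()
    assert macro_f1["rf"] > macro_f1["nn"]
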