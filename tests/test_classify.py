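"""Train/test splitting, grid/random hyperparameter search, prediction."""

import numpy as np
import pytest

from oilauth import (
    MixtureDesign,
    NNSearchSpace,
    RFSearchSpace,
    build_training_corpus,
    fit_random_forest,
    predict,
    split_train_test,
    train_neural_network,
    tune_random_forest,
)
from oilauth.generators import LabeledSimDataset

from conftest import separated_distributions

SMALL_RF_SPACE = RFSearchSpace(
    max_depth=(None,), bootstrap=(True,), max_features=("sqrt",),
    min_samples_split=(2,), min_samples_leaf=(1,), n_estimators=(30,),
    cv_folds=3,
)


@pytest.fixture(scope="module")
def separated_split():
    co, so = separated_distributions(k=10)
    corpus = build_training_corpus(co, so, MixtureDesign(n_per_class=100), seed=0)
    return split_train_test(corpus, 0.8, seed=1)


class TestSplit:
    def test_split_arithmetic(self, bundle):
        corpus = build_training_corpus(
            bundle.ground_truth["CO"], bundle.ground_truth["SO"],
            MixtureDesign(n_per_class=1000), seed=0,
        )
        split = split_train_test(corpus, 0.8, seed=0)
        assert split.X_train.shape == (5600, 37)
        assert split.X_test.shape == (1400, 37)
        # stratified: each class contributes 800/200 within 1 row
        for cls in split.class_order:
            assert abs((split.y_train == cls).sum() - 800) <= 1
            assert abs((split.y_test == cls).sum() - 200) <= 1

    def test_minimal_stratification(self):
        corpus = [
            LabeledSimDataset(lbl, np.random.default_rng(i).normal(size=(2, 3)),
                              "mc", i)
            for i, lbl in enumerate(["A", "B"])
        ]
        split = split_train_test(corpus, 0.5, seed=0)
        for cls in ("A", "B"):
            assert (split.y_train == cls).sum() == 1
            assert (split.y_test == cls).sum() == 1

    def test_seeded_determinism(self, separated_split):
        co, so = separated_distributions(k=10)
        corpus = build_training_corpus(co, so, MixtureDesign(n_per_class=100),
                                       seed=0)
        again = split_train_test(corpus, 0.8, seed=1)
        np.testing.assert_array_equal(again.X_train, separated_split.X_train)
        np.testing.assert_array_equal(again.y_test, separated_split.y_test)

    def test_singleton_class_rejected(self):
        corpus = [LabeledSimDataset("A", np.zeros((1, 3)), "mc", 0),
                  LabeledSimDataset("B", np.zeros((5, 3)), "mc", 0)]
        with pytest.raises(ValueError, match="stratification"):
            split_train_test(corpus, 0.5, seed=0)

    def test_bad_fraction_rejected(self, separated_split):
        with pytest.raises(ValueError, match="fraction"):
            split_train_test([], 1.0, seed=0)


class TestRandomForest:
    def test_single_combination_grid(self, separated_split):
        trained = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=0)
        assert trained.kind == "RF"
        assert trained.chosen_hyperparameters["n_estimators"] == 30
        assert len(trained.search_trace) == 1

    def test_grid_cardinality_and_tie_break(self, separated_split):
        space = RFSearchSpace(
            max_depth=(None, 5), bootstrap=(True,), max_features=("sqrt",),
            min_samples_split=(2,), min_samples_leaf=(1,),
            n_estimators=(10, 20), cv_folds=2,
        )
        trained = tune_random_forest(separated_split, space, seed=0)
        assert len(trained.search_trace) == 4  # 2 x 2 grid, each CV-scored
        # perfectly separable data ties every combination at 1.0:
        # first in enumeration order (max_depth=None, n_estimators=10) wins
        assert trained.training_accuracy_cv == pytest.approx(1.0)
        assert trained.chosen_hyperparameters["max_depth"] is None
        assert trained.chosen_hyperparameters["n_estimators"] == 10

    def test_separable_cv_accuracy(self, separated_split):
        trained = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=0)
        assert trained.training_accuracy_cv >= 0.99

    def test_deterministic_choice_and_predictions(self, separated_split):
        a = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=3)
        b = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=3)
        assert a.chosen_hyperparameters == b.chosen_hyperparameters
        np.testing.assert_array_equal(
            predict(a, separated_split.X_test), predict(b, separated_split.X_test)
        )

    def test_memorization_sanity(self, separated_split):
        trained = fit_random_forest(
            separated_split,
            dict(n_estimators=30, max_depth=None, max_features="sqrt",
                 min_samples_split=2, min_samples_leaf=1, bootstrap=False),
            seed=0,
        )
        preds = predict(trained, separated_split.X_train)
        assert (preds == separated_split.y_train).all()

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            RFSearchSpace(n_estimators=())


class TestNeuralNetwork:
    def test_single_trial_architecture(self, separated_split):
        space = NNSearchSpace(n_hidden_layers=(2, 2), hidden_dim=(16,),
                              batch_size=(32,), n_trials=1, epoch_budget=30)
        trained = train_neural_network(separated_split, space, seed=0)
        assert trained.kind == "NN"
        assert trained.chosen_hyperparameters["hidden_layer_sizes"] == (16, 16)
        assert trained.chosen_hyperparameters["batch_size"] == 32

    def test_output_width_matches_classes(self, separated_split):
        space = NNSearchSpace(n_hidden_layers=(1, 1), hidden_dim=(16,),
                              batch_size=(32,), n_trials=1, epoch_budget=20)
        trained = train_neural_network(separated_split, space, seed=0)
        assert trained.model.n_outputs_ == 7
        assert trained.n_features == 10

    def test_separable_validation_accuracy(self, separated_split):
        space = NNSearchSpace(n_hidden_layers=(1, 2), hidden_dim=(16, 32),
                              batch_size=(32,), n_trials=3, epoch_budget=60)
        trained = train_neural_network(separated_split, space, seed=0)
        assert trained.training_accuracy_cv >= 0.95

    def test_standardization_round_trip(self, separated_split):
        space = NNSearchSpace(n_hidden_layers=(1, 1), hidden_dim=(8,),
                              batch_size=(32,), n_trials=1, epoch_budget=10)
        trained = train_neural_network(separated_split, space, seed=0)
        X = separated_split.X_test
        hand = (X - separated_split.X_train.mean(axis=0)) / \
            separated_split.X_train.std(axis=0)
        np.testing.assert_allclose(trained.scaler.transform(X), hand, rtol=1e-10)


class TestPredict:
    def test_width_mismatch_rejected(self, separated_split):
        trained = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=0)
        with pytest.raises(ValueError, match="expected"):
            predict(trained, np.zeros((3, 5)))

    def test_duplicated_row_duplicated_prediction(self, separated_split):
        trained = tune_random_forest(separated_split, SMALL_RF_SPACE, seed=0)
        row = separated_split.X_test[:1]
        preds = predict(trained, np.vstack([row, row]))
        assert preds[0] == preds[1]
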