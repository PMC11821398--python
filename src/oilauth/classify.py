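"""Classifier training and hyperparameter tuning on the simulated corpus.

Two model families detect and quantify adulteration from the 37
compositional features:

* a Random Forest tuned by exhaustive grid search with stratified
  k-fold cross-validation over six hyperparameters (tree depth,
  bootstrap, features per split, split/leaf minima, forest size);
* a fully connected feed-forward network (input width = number of
  features, ReLU hidden layers, output width = number of classes,
  cross-entropy loss, Adam mini-batch training) tuned by randomized
  search over the number of hidden layers, the hidden-layer width and
  the batch size, scored on a validation split carved from the
  training data.

Features are standardized (train-set mean/SD) for the network only; the
forest is invariant to monotone feature scaling.  Grid enumeration
order is the declared field order of :class:`RFSearchSpace` with each
list in its declared order (itertools.product, last field fastest);
ties in CV accuracy keep the first combination encountered.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .generators import LabeledSimDataset


@dataclass(frozen=True)
class SplitCorpus:
    """Stratified train/test split of a labeled corpus."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    fraction: float
    seed: int
    class_order: tuple[str, ...]


@dataclass(frozen=True)
class RFSearchSpace:
    """Grid of Random-Forest hyperparameters (all lists non-empty).

    Defaults are a compact, replaceable grid over the six tuned
    dimensions.
    """

    max_depth: tuple[Optional[int], ...] = (None, 10, 30)
    bootstrap: tuple[bool, ...] = (True, False)
    max_features: tuple = ("sqrt", None)
    min_samples_split: tuple[int, ...] = (2, 5)
    min_samples_leaf: tuple[int, ...] = (1, 2)
    n_estimators: tuple[int, ...] = (100, 300)
    cv_folds: int = 5

    _FIELDS = (
        "max_depth", "bootstrap", "max_features",
        "min_samples_split", "min_samples_leaf", "n_estimators",
    )

    def __post_init__(self):
        for name in self._FIELDS:
            if not getattr(self, name):
                raise ValueError(f"search-space list {name!r} must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def combinations(self):
        """All grid points in documented enumeration order."""
        lists = [getattr(self, name) for name in self._FIELDS]
        for combo in itertools.product(*lists):
            yield dict(zip(self._FIELDS, combo))


@dataclass(frozen=True)
class NNSearchSpace:
    """Randomized-search space for the feed-forward network."""

    n_hidden_layers: tuple[int, int] = (1, 3)        # inclusive range
    hidden_dim: tuple[int, ...] = (32, 64, 128)      # choices per layer
    batch_size: tuple[int, ...] = (64, 256)
    n_trials: int = 20
    epoch_budget: int = 50
    validation_fraction: float = 0.1

    def __post_init__(self):
        lo, hi = self.n_hidden_layers
        if lo < 1 or hi < lo:
            raise ValueError("n_hidden_layers must be a non-empty range with lo >= 1")
        if not self.hidden_dim or not self.batch_size:
            raise ValueError("hidden_dim and batch_size choices must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrainedClassifier:
    """A fitted model plus everything needed to reproduce its predictions."""

    kind: str  # "RF" or "NN"
    model: object
    chosen_hyperparameters: dict
    training_accuracy_cv: float
    class_order: tuple[str, ...]
    seed: int
    scaler: Optional[StandardScaler] = None
    search_trace: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return int(self.model.n_features_in_)


def corpus_to_arrays(corpus: Sequence[LabeledSimDataset]):
    """Stack a list of labeled datasets into (X, y, class_order)."""
    X = np.vstack([d.data for d in corpus])
    y = np.concatenate([[d.label] * d.n for d in corpus])
    return X, y, tuple(d.label for d in corpus)


def split_train_test(
    corpus: Sequence[LabeledSimDataset], fraction: float = 0.8, seed: int = 0
) -> SplitCorpus:
    """Stratified random split into ``fraction`` train / rest test."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    X, y, order = corpus_to_arrays(corpus)
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError(
            f"every class needs >= 2 rows for stratification; "
            f"smallest is {counts.idxmin()!r} with {counts.min()}"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=fraction, stratify=y, random_state=seed
    )
    return SplitCorpus(X_tr, y_tr, X_te, y_te, fraction, seed, order)


def _make_rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def fit_random_forest(
    split: SplitCorpus, params: dict, seed: int
) -> TrainedClassifier:
    """Fit a forest with fixed hyperparameters on the full training set.

    This is the tuner's refit path, exposed directly for workflows that
    skip the grid search (e.g. large-corpus scaling runs with one
    pre-chosen configuration).
    """
    model = _make_rf(params, seed)
    model.fit(split.X_train, split.y_train)
    acc = float(model.score(split.X_train, split.y_train))
    return TrainedClassifier(
        "RF", model, dict(params), acc, split.class_order, seed
    )


def tune_random_forest(
    split: SplitCorpus, space: RFSearchSpace = RFSearchSpace(), seed: int = 0
) -> TrainedClassifier:
    """Exhaustive grid search by cross-validated accuracy, then refit.

    Every combination of the space is scored by stratified k-fold CV
    accuracy on the training set only; the best (first encountered on
    ties) is refit on the full training set.
    """
    cv = StratifiedKFold(n_splits=space.cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(split.X_train, split.y_train))
    best_params, best_acc = None, -np.inf
    trace = []
    for params in space.combinations():
        accs = []
        for tr_idx, va_idx in folds:
            m = _make_rf(params, seed)
            m.fit(split.X_train[tr_idx], split.y_train[tr_idx])
            accs.append(m.score(split.X_train[va_idx], split.y_train[va_idx]))
        acc = float(np.mean(accs))
        trace.append({**params, "cv_accuracy": acc})
        if acc > best_acc:
            best_acc, best_params = acc, params
    model = _make_rf(best_params, seed)
    model.fit(split.X_train, split.y_train)
    return TrainedClassifier(
        "RF", model, dict(best_params), best_acc, split.class_order, seed,
        search_trace=pd.DataFrame(trace),
    )


def _make_nn(params: dict, epoch_budget: int, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=params["hidden_layer_sizes"],
        batch_size=params["batch_size"],
        activation="relu",
        solver="adam",
        max_iter=epoch_budget,
        random_state=seed,
        # run the full epoch budget; no early stop on plateau
        tol=0.0,
        n_iter_no_change=epoch_budget,
    )


def train_neural_network(
    split: SplitCorpus, space: NNSearchSpace = NNSearchSpace(), seed: int = 0
) -> TrainedClassifier:
    """Randomized hyperparameter search for the feed-forward network.

    Draws ``n_trials`` configurations (hidden-layer count, one width per
    layer, batch size), trains each for the epoch budget on 90 % of the
    training data, scores accuracy on the held-out 10 %, then refits the
    best configuration on the full training set.  Standardization
    parameters always come from the data the model is fit on.
    """
    rng = np.random.default_rng(seed)
    X_fit, X_val, y_fit, y_val = train_test_split(
        split.X_train, split.y_train,
        test_size=space.validation_fraction, stratify=split.y_train,
        random_state=seed,
    )
    scaler_fit = StandardScaler().fit(X_fit)
    Xf, Xv = scaler_fit.transform(X_fit), scaler_fit.transform(X_val)

    lo, hi = space.n_hidden_layers
    best_params, best_acc = None, -np.inf
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for trial in range(space.n_trials):
            n_layers = int(rng.integers(lo, hi + 1))
            layers = tuple(int(rng.choice(space.hidden_dim)) for _ in range(n_layers))
            batch = int(rng.choice(space.batch_size))
            params = {"hidden_layer_sizes": layers, "batch_size": batch}
            m = _make_nn(params, space.epoch_budget, seed + trial)
            m.fit(Xf, y_fit)
            acc = float(m.score(Xv, y_val))
            trace.append(
                {"trial": trial, "hidden_layer_sizes": layers,
                 "batch_size": batch, "val_accuracy": acc}
            )
            if np.isnan(acc) or not np.isfinite(m.loss_):
                raise FloatingPointError(f"non-finite loss in trial {trial}")
            if acc > best_acc:
                best_acc, best_params = acc, params

        scaler = StandardScaler().fit(split.X_train)
        model = _make_nn(best_params, space.epoch_budget, seed)
        model.fit(scaler.transform(split.X_train), split.y_train)
    return TrainedClassifier(
        "NN", model, dict(best_params), best_acc, split.class_order, seed,
        scaler=scaler, search_trace=pd.DataFrame(trace),
    )


def predict(model: TrainedClassifier, data: np.ndarray) -> np.ndarray:
    """Predict one class label per row; deterministic for a fixed model."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != model.n_features:
        raise ValueError(
            f"expected n x {model.n_features} matrix, got shape {data.shape}"
        )
    if model.scaler is not None:
        data = model.scaler.transform(data)
    return np.asarray(model.model.predict(data))
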