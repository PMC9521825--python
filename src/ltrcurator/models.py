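"""Classifier zoo for the curation problem.

Three families are trained on the labeled datasets, for both the
five-label and the binarized two-label problem:

* classical ML with a fixed hyper-parameter grid (KNN, SVC, LR, LDA, NB,
  MLP, DT, RF), selected by validation F1;
* a fully-connected network (FNN) on PCA-reduced k-mer spectra — hidden
  stack with batch normalization (momentum 0.99), dropout 0.5, trained
  200 epochs at batch size 128;
* a convolutional network (CNN) on the 5 x m one-hot encoding for the
  two-label problem — three conv stages with 64/32/32 filters, spatial
  dropout 0.2, batch normalization, average pooling, and a dense head
  with dropout 0.2, trained on a balanced per-class subsample.

Every trained model carries its preprocessing (k-mer config, scaler, PCA
or one-hot pad length) so raw sequences can be scored directly, plus its
seed, config and per-epoch training curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import _nn
from .features import (FeatureMatrix, KmerConfig, OneHotTensor, PcaModel,
                       apply_pca, apply_scaler, kmer_matrix, one_hot)
from .sim import SequenceRecord

__all__ = [
    "GRID_ALGORITHMS",
    "FnnConfig",
    "CnnConfig",
    "Preprocessor",
    "TrainedModel",
    "GridSearchResult",
    "enumerate_grid",
    "make_estimator",
    "grid_search",
    "train_fnn",
    "train_cnn",
    "predict",
    "save_model",
    "load_model",
    "history_frame",
]

GRID_ALGORITHMS = ("KNN", "SVC", "LR", "LDA", "NB", "MLP", "DT", "RF")


# ---------------------------------------------------------------------------
# classical-ML grid
# ---------------------------------------------------------------------------


def enumerate_grid(algorithm: str) -> list[dict]:
    """Deterministic hyper-parameter candidates for one algorithm.

    Ranges: KNN n_neighbors 1..100 step 1; SVC C 10..100 multiplicative
    step 10 (gamma fixed at 1e-6); LR C 0.1..1 step 0.1; LDA tol
    0.0001..0.001 step 0.0001; NB var_smoothing 1e-1..1e-19 by factor
    1e-2; MLP single hidden layer 50..500 step 50 (lbfgs, alpha 0.5);
    DT max_depth 1..10 step 1; RF n_estimators 10..100 step 10.
    """
    if algorithm == "KNN":
        return [{"n_neighbors": k} for k in range(1, 101)]
    if algorithm == "SVC":
        return [{"C": float(c), "gamma": 1e-6} for c in (10, 100)]
    if algorithm == "LR":
        return [{"C": round(0.1 * i, 1)} for i in range(1, 11)]
    if algorithm == "LDA":
        return [{"tol": round(1e-4 * i, 4)} for i in range(1, 11)]
    if algorithm == "NB":
        return [{"var_smoothing": 10.0 ** (-e)} for e in range(1, 20, 2)]
    if algorithm == "MLP":
        return [{"hidden_layer_sizes": (w,), "solver": "lbfgs", "alpha": 0.5}
                for w in range(50, 501, 50)]
    if algorithm == "DT":
        return [{"max_depth": d} for d in range(1, 11)]
    if algorithm == "RF":
        return [{"n_estimators": n} for n in range(10, 101, 10)]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "SVC":
        return SVC(random_state=seed, **params)
    if algorithm == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed, **params)
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if algorithm == "NB":
        return GaussianNB(**params)
    if algorithm == "MLP":
        return MLPClassifier(max_iter=500, random_state=seed, **params)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if len(np.unique(y_true)) <= 2 and set(np.unique(y_true)) <= {0, 1}:
        return float(f1_score(y_true, y_pred, average="binary", zero_division=0))
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


@dataclass
class GridSearchResult:
    algorithm: str
    best_params: dict
    best_score: float
    #: (params, validation F1) per candidate, in enumeration order
    table: list[tuple[dict, float]]
    best_estimator: object = None


def grid_search(algorithm: str, X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                seed: int = 0) -> GridSearchResult:
    """Fit every grid candidate and keep the one with the highest
    validation F1; ties resolve to the earlier (smaller) candidate."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    best = None
    table = []
    for params in enumerate_grid(algorithm):
        est = make_estimator(algorithm, params, seed).fit(X_train, y_train)
        score = _f1(np.asarray(y_val), est.predict(X_val))
        table.append((params, score))
        if best is None or score > best[1]:
            best = (params, score, est)
    return GridSearchResult(algorithm, best[0], best[1], table, best[2])


# ---------------------------------------------------------------------------
# network configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FnnConfig:
    """Fully-connected network on (reduced) k-mer spectra."""

    hidden_layers: tuple[int, ...] = (256, 128, 64)
    activation: str = "relu"
    dropout: float = 0.5
    batchnorm_momentum: float = 0.99
    loss: str = "binary_ce"  # or "categorical_ce"
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("binary_ce", "categorical_ce"):
            raise ValueError("loss must be binary_ce or categorical_ce")
        if self.activation not in ("relu", "sigmoid", "tanh"):
            raise ValueError("activation must be relu, sigmoid or tanh")


@dataclass(frozen=True)
class CnnConfig:
    """Convolutional network on the 5 x m one-hot plane (two-label only)."""

    conv_filters: tuple[int, int, int] = (64, 32, 32)
    kernel_sizes: tuple[tuple[int, int], ...] = ((5, 5), (3, 3), (3, 3))
    spatial_dropout: float = 0.2
    pool_size: tuple[int, int] = (1, 2)
    head: FnnConfig = field(default_factory=lambda: FnnConfig(
        hidden_layers=(64,), dropout=0.2, loss="binary_ce"))
    subsample_per_class: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("exactly three convolutional stages")
        if self.subsample_per_class < 1:
            raise ValueError("subsample_per_class must be >= 1")


# ---------------------------------------------------------------------------
# preprocessing bound to models
# ---------------------------------------------------------------------------


@dataclass
class Preprocessor:
    """Featurization state bound to a trained model at train time."""

    kind: str  # "kmer" or "onehot"
    kmer_config: Optional[KmerConfig] = None
    scaler: object = None
    pca: Optional[PcaModel] = None
    m: Optional[int] = None  # one-hot pad/crop length

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            X = apply_scaler(self.scaler, X)
        if self.pca is not None:
            X = apply_pca(self.pca, X)
        return X

    def transform_records(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        if self.kind == "kmer":
            X = kmer_matrix(records, self.kmer_config or KmerConfig()).X
            return self.transform_features(X)
        tensor = one_hot(records)
        return tensor_to_input(tensor, self.m)


def tensor_to_input(tensor: OneHotTensor, m: Optional[int] = None) -> np.ndarray:
    """(5, m, n) one-hot stack -> (n, 1, 5, m) network input, padded or
    cropped on the right to a fixed width when ``m`` is given."""
    X = np.moveaxis(tensor.X, 2, 0)[:, None, :, :]
    if m is not None and m != X.shape[3]:
        if m > X.shape[3]:
            pad = np.zeros((X.shape[0], 1, 5, m - X.shape[3]), dtype=X.dtype)
            X = np.concatenate([X, pad], axis=3)
        else:
            X = X[:, :, :, :m]
    return np.ascontiguousarray(X, dtype=float)


@dataclass
class TrainedModel:
    kind: str  # "fnn", "cnn" or "sklearn"
    model: object
    classes: np.ndarray
    config: object = None
    seed: int = 0
    preprocessing: Optional[Preprocessor] = None
    history: list[dict] = field(default_factory=list)
    algorithm: Optional[str] = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def history_frame(model: TrainedModel) -> pd.DataFrame:
    """Training curves as a tidy table (epoch, train/val loss, val metric)."""
    return pd.DataFrame(model.history)


# ---------------------------------------------------------------------------
# network training
# ---------------------------------------------------------------------------


def _encode_targets(y: np.ndarray, classes: np.ndarray, loss: str) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    if loss == "categorical_ce":
        out = np.zeros((len(y), len(classes)))
        out[np.arange(len(y)), idx] = 1.0
        return out
    if len(classes) != 2:
        raise ValueError("binary_ce requires exactly two classes")
    return (idx == 1).astype(float)[:, None]


def _val_f1(classes: np.ndarray):
    def metric(net: _nn.Network, xv: np.ndarray, yv: np.ndarray) -> float:
        p = net.predict_proba(xv)
        if p.shape[1] == 1:
            pred = classes[(p[:, 0] >= 0.5).astype(int)]
            true = classes[(yv[:, 0] >= 0.5).astype(int)]
        else:
            pred = classes[p.argmax(axis=1)]
            true = classes[yv.argmax(axis=1)]
        return _f1(true, pred)
    return metric


def _build_fnn_layers(n_in: int, n_out: int, config: FnnConfig,
                      rng: np.random.Generator) -> list[_nn.Layer]:
    layers: list[_nn.Layer] = []
    d = n_in
    for width in config.hidden_layers:
        layers.append(_nn.Dense(d, width, rng))
        layers.append(_nn.BatchNorm(width, config.batchnorm_momentum))
        layers.append(_nn.Activation(config.activation))
        layers.append(_nn.Dropout(config.dropout))
        d = width
    layers.append(_nn.Dense(d, n_out, rng))
    return layers


def _loss_for(config: FnnConfig):
    return (_nn.CategoricalCrossEntropy() if config.loss == "categorical_ce"
            else _nn.BinaryCrossEntropy())


def train_fnn(config: FnnConfig, train: tuple[np.ndarray, np.ndarray],
              validation: tuple[np.ndarray, np.ndarray] | None = None,
              preprocessing: Optional[Preprocessor] = None) -> TrainedModel:
    """Train the fully-connected network for exactly ``config.epochs``
    epochs at ``config.batch_size``, recording per-epoch validation F1 and
    loss.  Deterministic for a fixed seed (single-threaded numpy)."""
    X, y = np.asarray(train[0], dtype=float), np.asarray(train[1])
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    loss = _loss_for(config)
    rng = np.random.default_rng(config.seed)
    layers = _build_fnn_layers(X.shape[1], loss.n_outputs_for(len(classes)),
                               config, rng)
    net = _nn.Network(layers, loss, seed=config.seed + 1,
                      lr=config.learning_rate)
    yt = _encode_targets(y, classes, config.loss)
    val = None
    if validation is not None:
        val = (np.asarray(validation[0], dtype=float),
               _encode_targets(np.asarray(validation[1]), classes, config.loss))
    history = net.fit(X, yt, config.epochs, config.batch_size,
                      validation=val, metric=_val_f1(classes))
    return TrainedModel("fnn", net, classes, config, config.seed,
                        preprocessing, history)


def balanced_subsample(y: np.ndarray, per_class: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of exactly ``per_class`` records per class, without
    replacement; raises if any class is smaller than that."""
    y = np.asarray(y)
    keep = []
    for c in np.unique(y):
        pool = np.flatnonzero(y == c)
        if len(pool) < per_class:
            raise ValueError(f"class {c!r} has only {len(pool)} records "
                             f"(< {per_class})")
        keep.append(rng.choice(pool, size=per_class, replace=False))
    return np.sort(np.concatenate(keep))


def train_cnn(config: CnnConfig,
              train: tuple[OneHotTensor | np.ndarray, np.ndarray],
              validation: tuple[OneHotTensor | np.ndarray, np.ndarray] | None = None,
              preprocessing: Optional[Preprocessor] = None) -> TrainedModel:
    """Train the convolutional network on one-hot input (two-label problem).

    A balanced per-class subsample of the training pool is drawn first;
    epochs, batch size and the dense head come from ``config.head``."""
    def as_input(data):
        return tensor_to_input(data) if isinstance(data, OneHotTensor) \
            else np.asarray(data, dtype=float)

    X, y = as_input(train[0]), np.asarray(train[1])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("the CNN handles the two-label problem only")
    m = X.shape[3]
    if m < config.kernel_sizes[0][1]:
        raise ValueError("sequences shorter than the first kernel width")
    rng = np.random.default_rng(config.seed)
    per_class = min(config.subsample_per_class,
                    int(min(np.bincount(np.searchsorted(classes, y)))))
    idx = balanced_subsample(y, per_class, rng)
    X, y = X[idx], y[idx]

    loss = _loss_for(config.head)
    net_rng = np.random.default_rng(config.seed + 2)
    layers: list[_nn.Layer] = []
    c_in, h, w = 1, 5, m
    for filters, (kh, kw) in zip(config.conv_filters, config.kernel_sizes):
        layers.append(_nn.Conv2D(c_in, filters, kh, kw, net_rng))
        layers.append(_nn.Activation("relu"))
        layers.append(_nn.SpatialDropout(config.spatial_dropout))
        layers.append(_nn.BatchNorm(filters, config.head.batchnorm_momentum))
        layers.append(_nn.AvgPool2D(*config.pool_size))
        c_in = filters
        h //= config.pool_size[0]
        w //= config.pool_size[1]
        if h < 1 or w < 1:
            raise ValueError("feature map collapsed; reduce pooling")
    layers.append(_nn.Flatten())
    layers.extend(_build_fnn_layers(c_in * h * w,
                                    loss.n_outputs_for(len(classes)),
                                    config.head, net_rng))
    net = _nn.Network(layers, loss, seed=config.seed + 3,
                      lr=config.head.learning_rate)
    yt = _encode_targets(y, classes, config.head.loss)
    val = None
    if validation is not None:
        val = (as_input(validation[0]),
               _encode_targets(np.asarray(validation[1]), classes,
                               config.head.loss))
    history = net.fit(X, yt, config.head.epochs, config.head.batch_size,
                      validation=val, metric=_val_f1(classes))
    return TrainedModel("cnn", net, classes, config, config.seed,
                        preprocessing, history)


# ---------------------------------------------------------------------------
# prediction and persistence
# ---------------------------------------------------------------------------


def predict(model: TrainedModel,
            data: np.ndarray | FeatureMatrix | OneHotTensor | Sequence[SequenceRecord],
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class scores for new data.

    Raw ``SequenceRecord`` lists are featurized through the model's bound
    preprocessing; a ``FeatureMatrix`` is taken as raw k-mer features (the
    bound scaler/PCA are applied); a plain array is used as-is.  Binary
    scores are the probability of the positive class, thresholded at
    ``threshold`` (0.5 by default).
    """
    if isinstance(model.model, _nn.Network) and not model.model.fitted:
        raise RuntimeError("model is not fitted")
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], SequenceRecord):
        if model.preprocessing is None:
            raise ValueError("model has no bound preprocessing for raw sequences")
        X = model.preprocessing.transform_records(data)
    elif isinstance(data, FeatureMatrix):
        X = data.X
        if model.preprocessing is not None:
            X = model.preprocessing.transform_features(X)
    elif isinstance(data, OneHotTensor):
        X = tensor_to_input(data, model.preprocessing.m
                            if model.preprocessing else None)
    else:
        X = np.asarray(data, dtype=float)

    if model.kind == "sklearn":
        est = model.model
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X)
        else:
            pred = est.predict(X)
            scores = np.zeros((len(pred), len(model.classes)))
            scores[np.arange(len(pred)),
                   np.searchsorted(model.classes, pred)] = 1.0
        if len(model.classes) == 2:
            pos = scores[:, 1]
            return model.classes[(pos >= threshold).astype(int)], pos
        return model.classes[scores.argmax(axis=1)], scores

    probs = model.model.predict_proba(X)
    if probs.shape[1] == 1:
        pos = probs[:, 0]
        return model.classes[(pos >= threshold).astype(int)], pos
    return model.classes[probs.argmax(axis=1)], probs


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize model + preprocessing + config + seed provenance."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
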