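"""Localization classifiers: 1D-CNN, MLP, Random Forest; SMOTE; repeated CV.

The three model families mirror the study design:

* a 1D convolutional network reading the profile as a length-D
  single-channel signal (conv 128 filters kernel 3 -> maxpool 3 ->
  conv 256 kernel 3 -> maxpool 3 -> dense 256 + 30% dropout -> sigmoid);
* a multilayer perceptron with hidden widths 128/64/32 and a sigmoid
  output;
* a Random Forest with 100 trees whose score is the positive-class vote
  fraction.

Class imbalance is handled by SMOTE oversampling of the minority class
(default), by class-weighted training, or not at all.  The evaluation
protocol is stratified 5-fold cross-validation repeated twice, with
SMOTE applied inside each training fold only so synthetic rows never
reach a held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from . import nn
from .metrics import MetricsReport, compute_metrics

MODEL_KINDS = ("cnn1d", "mlp", "rf")


@dataclass(frozen=True)
class CNNSpec:
    conv_filters: tuple[int, int] = (128, 256)
    kernel: int = 3
    pool: int = 3
    dense_units: int = 256
    dropout: float = 0.3


@dataclass(frozen=True)
class MLPSpec:
    hidden: tuple[int, ...] = (128, 64, 32)


@dataclass(frozen=True)
class RFSpec:
    n_trees: int = 100

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic row is X_i + u * (X_j - X_i) with u ~ U[0, 1), where
    X_i is a random minority row and X_j one of its k nearest minority
    neighbors; original rows are preserved and come first in the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min <= k_neighbors:
        new_k = max(1, n_min - 1)
        warnings.warn(
            f"minority class has {n_min} samples <= k_neighbors="
            f"{k_neighbors}; reducing k to {new_k}")
        k_neighbors = new_k
    X_min = X[y == minority]
    nbrs = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, neighbor_idx = nbrs.kneighbors(X_min)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    gaps = rng.random(n_new)
    partners = neighbor_idx[base, pick]
    synthetic = X_min[base] + gaps[:, None] * (X_min[partners] - X_min[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


class _NeuralClassifier:
    """Thin wrapper giving nn.Network the score/predict surface."""

    def __init__(self, network: nn.Network, reshape_1d: bool):
        self.network = network
        self.reshape_1d = reshape_1d

    def scores(self, X: np.ndarray) -> np.ndarray:
        out = self.network.forward(np.asarray(X, dtype=float))
        return out.ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(np.int64)


class _ForestClassifier:
    def __init__(self, forest: RandomForestClassifier):
        self.forest = forest

    def scores(self, X: np.ndarray) -> np.ndarray:
        proba = self.forest.predict_proba(X)
        pos = list(self.forest.classes_).index(1)
        return proba[:, pos]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(np.int64)


def build_cnn(input_dim: int, spec: CNNSpec, seed: int = 0) -> nn.Network:
    """Assemble the 1D-CNN; layer lengths follow valid-conv/pool arithmetic."""
    rng = np.random.default_rng(seed)
    f1, f2 = spec.conv_filters
    length = input_dim
    layers: list[nn.Layer] = [nn.Reshape(1)]
    layers += [nn.Conv1D(1, f1, spec.kernel, rng), nn.ReLU()]
    length = length - spec.kernel + 1
    layers.append(nn.MaxPool1D(spec.pool))
    length //= spec.pool
    layers += [nn.Conv1D(f1, f2, spec.kernel, rng), nn.ReLU()]
    length = length - spec.kernel + 1
    layers.append(nn.MaxPool1D(spec.pool))
    length //= spec.pool
    if length < 1:
        raise ValueError(f"input_dim={input_dim} too short for the conv stack")
    layers.append(nn.Flatten())
    layers += [nn.Dense(length * f2, spec.dense_units, rng), nn.ReLU(),
               nn.Dropout(spec.dropout, rng)]
    layers += [nn.Dense(spec.dense_units, 1, rng), nn.Sigmoid()]
    return nn.Network(layers)


def build_mlp(input_dim: int, spec: MLPSpec, seed: int = 0) -> nn.Network:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    prev = input_dim
    for width in spec.hidden:
        layers += [nn.Dense(prev, width, rng), nn.ReLU()]
        prev = width
    layers += [nn.Dense(prev, 1, rng), nn.Sigmoid()]
    return nn.Network(layers)


def train_model(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0, *,
                spec=None, epochs: int = 50, batch_size: int = 32,
                lr: float = 1e-3, class_weight: bool = False):
    """Fit one classifier; the result exposes scores(X) in [0,1] and predict(X).

    ``class_weight=True`` weights samples inversely to class frequency
    (the alternative to SMOTE for imbalance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "rf":
        spec = spec or RFSpec()
        forest = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed,
            class_weight="balanced" if class_weight else None)
        forest.fit(X, y)
        return _ForestClassifier(forest)
    sample_weight = None
    if class_weight:
        counts = np.bincount(y, minlength=2)
        w = len(y) / (2.0 * counts)
        sample_weight = w[y]
    if kind == "cnn1d":
        spec = spec or CNNSpec()
        network = build_cnn(X.shape[1], spec, seed)
    elif kind == "mlp":
        spec = spec or MLPSpec()
        network = build_mlp(X.shape[1], spec, seed)
    else:
        raise ValueError(f"unknown model kind {kind!r}; expected {MODEL_KINDS}")
    network.fit(X, y.astype(float), epochs=epochs, batch_size=batch_size,
                lr=lr, seed=seed, sample_weight=sample_weight)
    return _NeuralClassifier(network, reshape_1d=(kind == "cnn1d"))


@dataclass
class CVResult:
    """Per-fold metric reports (folds x repeats) with mean/std aggregation."""

    reports: list[MetricsReport]
    folds: int
    repeats: int

    def __post_init__(self):
        if len(self.reports) != self.folds * self.repeats:
            raise ValueError("report count must equal folds * repeats")

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.reports]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(r, metric) for r in self.reports]))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m))
                for m in ("oa", "precision", "recall", "f1", "sn", "sp",
                          "mcc", "auc")}


def repeated_cv(kind: str, X: np.ndarray, y: np.ndarray, *, folds: int = 5,
                repeats: int = 2, seed: int = 0, imbalance: str = "smote",
                spec=None, **train_kw) -> CVResult:
    """Stratified k-fold CV repeated with independent shufflings.

    Oversampling (when ``imbalance='smote'``) is applied to each
    training fold only, never to the held-out fold.
    """
    if imbalance not in ("smote", "class-weight", "none"):
        raise ValueError(f"unknown imbalance strategy {imbalance!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold CV, "
            f"got counts {counts.tolist()}")
    reports = []
    for rep in range(repeats):
        rep_seed = seed * 1000 + rep
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=rep_seed % (2**31))
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            X_tr, y_tr = X[tr], y[tr]
            if imbalance == "smote":
                X_tr, y_tr = smote_oversample(X_tr, y_tr,
                                              seed=rep_seed + fold)
            model = train_model(kind, X_tr, y_tr,
                                seed=rep_seed + fold, spec=spec,
                                class_weight=(imbalance == "class-weight"),
                                **train_kw)
            scores = model.scores(X[te])
            reports.append(compute_metrics(y[te], model.predict(X[te]), scores))
    return CVResult(reports=reports, folds=folds, repeats=repeats)
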