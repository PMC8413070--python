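"""The four regression models and the train/test split.

Families
--------
LR   ordinary least-squares linear regression,
     y_i = b0 + b1 x_i1 + ... + bp x_ip + eps.
KNN  k-nearest-neighbors regression with inverse-Euclidean-distance
     weighting of the k closest training samples; a zero-distance query
     returns the mean label of its exact matches (the limit of 1/d
     weights).  k may be fixed, or grid-searched over 1..25 on a held-out
     slice of the training fold by validation PC.
RF   random forest: bagged regression trees, mean of leaf predictions.
ANN  multilayer perceptron with one hidden layer of sigmoid units.

All models are trained on per-column standardized features (scaler fitted
on the training fold and stored with the model) and predict on the raw
1-5 score scale.  Every stochastic fit is seeded, so training twice with
the same spec and data gives identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .metrics import pearson_correlation

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "TrainedRegressor",
    "split_dataset",
    "fit",
    "predict_knn",
    "default_specs",
]

MODEL_FAMILIES = ("LR", "KNN", "RF", "ANN")

#: k grid searched when a KNN spec leaves k unset.
KNN_K_GRID = tuple(range(1, 26))


@dataclass(frozen=True)
class ModelSpec:
    """Family + hyperparameters + seed for one regressor.

    KNN: ``k`` (None = grid-search 1..25 by validation PC), ``weighting``
    in {"distance", "uniform"}.  RF: ``n_trees``, ``max_features``.
    ANN: ``hidden_layer_sizes``, sigmoid activation, ``max_epochs`` with
    early stopping on a 10% validation split.
    """

    family: str
    seed: int = 0
    # KNN
    k: int | None = None
    weighting: str = "distance"
    # RF
    n_trees: int = 200
    max_features: float = 1 / 3
    # ANN
    hidden_layer_sizes: tuple[int, ...] = (32,)
    max_epochs: int = 2000

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"expected one of {MODEL_FAMILIES}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")


def default_specs(seed: int = 0) -> dict[str, ModelSpec]:
    """One default spec per family, all seeded from ``seed``."""
    return {fam: ModelSpec(family=fam, seed=seed) for fam in MODEL_FAMILIES}


def split_dataset(n_or_rows, train_fraction: float = 0.8, seed: int = 0):
    """Seeded disjoint, exhaustive train/test partition.

    Given an integer n, returns (train_idx, test_idx) index arrays with
    round(n * train_fraction) training rows; given a sequence, returns the
    partitioned (train_rows, test_rows).  The same seed always produces the
    same split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if isinstance(n_or_rows, (int, np.integer)):
        n = int(n_or_rows)
        rows = None
    else:
        rows = list(n_or_rows)
        n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if rows is None:
        return train_idx, test_idx
    return [rows[i] for i in train_idx], [rows[i] for i in test_idx]


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entry in training data")
    return X, y


@dataclass
class TrainedRegressor:
    """A fitted model plus the feature scaler captured at fit time."""

    spec: ModelSpec
    estimator: object
    scaler: StandardScaler

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite entry in prediction input")
        return np.asarray(self.estimator.predict(self.scaler.transform(X)),
                          dtype=float)


def _select_k(Xs: np.ndarray, y: np.ndarray, spec: ModelSpec) -> int:
    """Grid-search k over 1..25 by PC on a 25% validation slice of the fold."""
    n = Xs.shape[0]
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_val = max(1, n // 4)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size < 2:
        return 1
    best_k, best_pc = 1, -np.inf
    for k in KNN_K_GRID:
        if k > tr_idx.size:
            break
        est = KNeighborsRegressor(n_neighbors=k, weights=spec.weighting)
        est.fit(Xs[tr_idx], y[tr_idx])
        pc = pearson_correlation(y[val_idx], est.predict(Xs[val_idx]))
        if np.isfinite(pc) and pc > best_pc:
            best_pc, best_k = pc, k
    return best_k


def fit(spec: ModelSpec, X, y) -> TrainedRegressor:
    """Fit one model on (X, y); features standardized per column internally."""
    X, y = _validate_xy(X, y)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if spec.family == "LR":
        est = LinearRegression()
    elif spec.family == "KNN":
        k = spec.k if spec.k is not None else _select_k(Xs, y, spec)
        if k > X.shape[0]:
            raise ValueError(f"k={k} exceeds the {X.shape[0]} training rows")
        est = KNeighborsRegressor(n_neighbors=k, weights=spec.weighting)
        spec = replace(spec, k=k)
    elif spec.family == "RF":
        est = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=spec.max_features,
            random_state=spec.seed,
        )
    else:  # ANN
        # early stopping needs a usable 10% validation slice
        est = MLPRegressor(
            hidden_layer_sizes=spec.hidden_layer_sizes,
            activation="logistic",
            max_iter=spec.max_epochs,
            early_stopping=X.shape[0] >= 50,
            validation_fraction=0.1,
            random_state=spec.seed,
        )
    est.fit(Xs, y)
    return TrainedRegressor(spec=spec, estimator=est, scaler=scaler)


def predict_knn(
    X_train,
    y_train,
    query,
    k: int,
    weighting: str = "distance",
) -> float:
    """Inverse-distance-weighted k-NN prediction for a single query point.

    The k nearest training rows (Euclidean distance) vote with weights 1/d
    ("distance") or equally ("uniform"); if the query coincides with
    training points, the mean label of the zero-distance matches is
    returned (the limit of 1/d weighting).
    """
    X_train, y_train = _validate_xy(X_train, y_train)
    if not 1 <= k <= X_train.shape[0]:
        raise ValueError(f"k={k} out of range 1..{X_train.shape[0]}")
    q = np.asarray(query, dtype=float).ravel()
    d = np.sqrt(((X_train - q) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[:k]
    dn, yn = d[nearest], y_train[nearest]
    if weighting == "uniform":
        return float(yn.mean())
    if weighting != "distance":
        raise ValueError(f"unknown weighting {weighting!r}")
    if (dn == 0).any():
        return float(yn[dn == 0].mean())
    w = 1.0 / dn
    return float((w * yn).sum() / w.sum())
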