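"""The 1D-CNN phenotype regressor: architecture spec, training, prediction.

The default architecture stacks four same-padded 1D convolutional layers
(16, 32, 64 and 128 filters; kernel sizes 5, 5, 3, 3), each with ReLU,
LeCun-normal initialisation and an L1+L2 kernel penalty, followed by a
single max-pooling layer (window 2, stride 2) that halves the sequence
length, a flatten layer, dropout (rate 0.6) and one dense output neuron.
Training minimises mean absolute error with Adam (learning rate 3e-4) for at
most 150 epochs, with early stopping on validation MAE that restores the
best epoch's weights.

Input is the one-hot genotype tensor (accessions x markers x channels);
output is one real phenotype value per accession.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .encoding import GenotypeTensor

__all__ = [
    "ModelSpec",
    "LayerShape",
    "TrainedModel",
    "default_spec",
    "feature_shapes",
    "build_network",
    "build_and_fit",
    "predict",
    "save_model",
    "load_model",
    "NovGMDeepRegressor",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture and optimisation configuration."""

    conv_layers: tuple[tuple[int, int], ...] = ((16, 5), (32, 5), (64, 3), (128, 3))
    pool: tuple[int, int] | None = (2, 2)  # (window, stride)
    dropout_rate: float = 0.6
    dense_units: int = 1
    l1: float = 1e-4
    l2: float = 1e-4
    learning_rate: float = 0.0003
    max_epochs: int = 150
    batch_size: int = 32
    early_stopping_patience: int = 30
    scale_phenotype: bool = False  # optional z-scoring, inverted before metrics

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for _, k in self.conv_layers:
            if k % 2 != 1:
                raise ValueError("same padding requires odd kernel sizes")
        if self.pool is not None and self.pool != (2, 2):
            raise ValueError("only (window 2, stride 2) pooling is supported")


def default_spec() -> ModelSpec:
    """The reference architecture and optimiser settings."""
    return ModelSpec()


@dataclass(frozen=True)
class LayerShape:
    layer_name: str
    length: int
    channels: int


def feature_shapes(
    spec: ModelSpec, input_length: int, input_channels: int
) -> list[LayerShape]:
    """Per-layer output shapes for a given input (markers x channels).

    Same-padded convolutions preserve length; the pool halves it (floor);
    flatten yields ``last_filters * floor(L/2)`` units; the dense layer
    yields one output.
    """
    if input_length < 2:
        raise ValueError(f"input_length must be >= 2, got {input_length}")
    if input_channels < 1:
        raise ValueError("input_channels must be >= 1")
    shapes: list[LayerShape] = []
    length, channels = input_length, input_channels
    for i, (filters, kernel) in enumerate(spec.conv_layers, start=1):
        channels = filters
        shapes.append(LayerShape(f"conv{i} (k={kernel})", length, channels))
    if spec.pool is not None:
        length = length // 2
        shapes.append(LayerShape("maxpool", length, channels))
    shapes.append(LayerShape("flatten", length * channels, 1))
    shapes.append(LayerShape("dense", spec.dense_units, 1))
    return shapes


def model_param_count(spec: ModelSpec, input_length: int, input_channels: int) -> int:
    """Closed-form trainable-parameter count of the built network."""
    total = 0
    c_in = input_channels
    length = input_length
    for filters, kernel in spec.conv_layers:
        total += kernel * c_in * filters + filters
        c_in = filters
    if spec.pool is not None:
        length = length // 2
    total += length * c_in * spec.dense_units + spec.dense_units
    return total


def build_network(
    spec: ModelSpec, input_length: int, input_channels: int, seed: int = 0
) -> nn.Network:
    """Instantiate the layer stack with seeded LeCun-normal weights."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = input_channels
    length = input_length
    for filters, kernel in spec.conv_layers:
        layers.append(nn.Conv1DSame(c_in, filters, kernel, rng, l1=spec.l1, l2=spec.l2))
        layers.append(nn.ReLU())
        c_in = filters
    if spec.pool is not None:
        layers.append(nn.MaxPool1D())
        length = length // 2
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout_rate, rng))
    layers.append(nn.Dense(length * c_in, spec.dense_units, rng, l1=spec.l1, l2=spec.l2))
    return nn.Network(layers)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse or audit it."""

    spec: ModelSpec
    network: nn.Network
    input_shape: tuple[int, int]  # (markers, channels)
    history: pd.DataFrame  # columns epoch, train_mae, val_mae
    best_epoch: int
    best_val_mae: float
    seed: int
    y_center: float = 0.0  # z-scoring parameters (identity when disabled)
    y_scale: float = 1.0


def _as_array(tensor) -> np.ndarray:
    if isinstance(tensor, GenotypeTensor):
        return tensor.data
    return np.asarray(tensor)


def build_and_fit(
    spec: ModelSpec,
    train: tuple,
    val: tuple,
    seed: int = 0,
) -> TrainedModel:
    """Build the network and train it on (tensor, phenotypes) pairs.

    Early stopping monitors validation MAE; the returned model carries the
    weights of the epoch with the lowest validation MAE and the full loss
    history. Weight initialisation, shuffling and dropout are all driven by
    ``seed``, so identical calls produce identical histories.
    """
    X_train = _as_array(train[0])
    X_val = _as_array(val[0])
    y_train = np.asarray(train[1], dtype=float)
    y_val = np.asarray(val[1], dtype=float)
    if X_train.ndim != 3 or X_val.ndim != 3:
        raise ValueError("genotype tensors must be 3D (accessions, markers, channels)")
    if X_train.shape[1:] != X_val.shape[1:]:
        raise ValueError(
            f"train/val tensor shapes differ: {X_train.shape[1:]} vs {X_val.shape[1:]}"
        )
    if not (np.isfinite(y_train).all() and np.isfinite(y_val).all()):
        raise ValueError("phenotype vectors must be finite")

    center, scale = 0.0, 1.0
    if spec.scale_phenotype:
        center = float(y_train.mean())
        scale = float(y_train.std()) or 1.0
    yt = (y_train - center) / scale
    yv = (y_val - center) / scale

    L, C = X_train.shape[1], X_train.shape[2]
    net = build_network(spec, L, C, seed=seed)
    optimizer = nn.Adam(net.params, lr=spec.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    hist = nn.fit_mae(
        net,
        optimizer,
        X_train,
        yt,
        X_val,
        yv,
        max_epochs=spec.max_epochs,
        batch_size=spec.batch_size,
        patience=spec.early_stopping_patience,
        rng=rng,
    )
    history = pd.DataFrame(
        {
            "epoch": np.arange(1, len(hist["train_mae"]) + 1),
            "train_mae": np.asarray(hist["train_mae"]) * scale,
            "val_mae": np.asarray(hist["val_mae"]) * scale,
        }
    )
    return TrainedModel(
        spec=spec,
        network=net,
        input_shape=(L, C),
        history=history,
        best_epoch=hist["best_epoch"],
        best_val_mae=hist["best_val_mae"] * scale,
        seed=seed,
    y_center=center,
        y_scale=scale,
    )


def predict(model: TrainedModel, tensor) -> np.ndarray:
    """Deterministic per-accession predictions (dropout inactive)."""
    X = _as_array(tensor)
    if X.ndim != 3 or X.shape[1:] != model.input_shape:
        raise ValueError(
            f"tensor shape mismatch: expected (*, {model.input_shape[0]}, "
            f"{model.input_shape[1]}), got {X.shape}"
        )
    raw = model.network.forward(X, training=False)
    return raw.astype(float) * model.y_scale + model.y_center


def save_model(model: TrainedModel, path: str | Path) -> tuple[Path, Path]:
    """Serialise weights (.npz) plus a JSON manifest; see :func:`load_model`."""
    path = Path(path)
    npz = path.with_suffix(".npz")
    manifest = path.with_suffix(".json")
    np.savez(npz, *model.network.params)
    spec_dict = asdict(model.spec)
    spec_dict["conv_layers"] = [list(c) for c in model.spec.conv_layers]
    manifest.write_text(
        json.dumps(
            {
                "spec": spec_dict,
                "input_shape": list(model.input_shape),
                "best_epoch": model.best_epoch,
                "best_val_mae": model.best_val_mae,
                "seed": model.seed,
                "y_center": model.y_center,
                "y_scale": model.y_scale,
                "history": model.history.to_dict(orient="list"),
            }
        )
    )
    return npz, manifest


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_dict = dict(meta["spec"])
    spec_dict["conv_layers"] = tuple(tuple(c) for c in spec_dict["conv_layers"])
    if spec_dict.get("pool") is not None:
        spec_dict["pool"] = tuple(spec_dict["pool"])
    spec = ModelSpec(**spec_dict)
    L, C = meta["input_shape"]
    net = build_network(spec, L, C, seed=meta["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        net.set_weights([data[k] for k in data.files])
    return TrainedModel(
        spec=spec,
        network=net,
        input_shape=(L, C),
        history=pd.DataFrame(meta["history"]),
        best_epoch=meta["best_epoch"],
        best_val_mae=meta["best_val_mae"],
        seed=meta["seed"],
        y_center=meta["y_center"],
        y_scale=meta["y_scale"],
    )


class NovGMDeepRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn style wrapper around the 1D-CNN phenotype regressor.

    ``X`` is the 3D one-hot genotype tensor ``(n_accessions, n_markers,
    n_channels)``. If no validation set is passed to :meth:`fit`, a fraction
    of the training data (``validation_fraction``) is held out for early
    stopping.

    Examples
    --------
    >>> reg = NovGMDeepRegressor(max_epochs=20, random_state=0)
    >>> reg.fit(X, y).predict(X_new)  # doctest: +SKIP
    """

    def __init__(
        self,
        conv_layers=((16, 5), (32, 5), (64, 3), (128, 3)),
        pool=(2, 2),
        dropout_rate: float = 0.6,
        l1: float = 1e-4,
        l2: float = 1e-4,
        learning_rate: float = 0.0003,
        max_epochs: int = 150,
        batch_size: int = 32,
        early_stopping_patience: int = 30,
        scale_phenotype: bool = False,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.conv_layers = conv_layers
        self.pool = pool
        self.dropout_rate = dropout_rate
        self.l1 = l1
        self.l2 = l2
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.early_stopping_patience = early_stopping_patience
        self.scale_phenotype = scale_phenotype
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            conv_layers=tuple(tuple(c) for c in self.conv_layers),
            pool=tuple(self.pool) if self.pool is not None else None,
            dropout_rate=self.dropout_rate,
            l1=self.l1,
            l2=self.l2,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            early_stopping_patience=self.early_stopping_patience,
            scale_phenotype=self.scale_phenotype,
        )

    def fit(self, X, y, validation_data: tuple | None = None):
        X = _as_array(X)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                "X must be a 3D one-hot genotype tensor "
                "(accessions, markers, channels)"
            )
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if validation_data is None:
            rng = np.random.default_rng(self.random_state)
            n = X.shape[0]
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            validation_data = (X[val_idx], y[val_idx])
            X, y = X[train_idx], y[train_idx]
        self.model_ = build_and_fit(
            self._spec(), (X, y), validation_data, seed=self.random_state
        )
        self.history_ = self.model_.history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        return predict(self.model_, X)
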