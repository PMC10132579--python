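"""Minimal NumPy engine for 1D convolutional regression networks.

Implements exactly the pieces the phenotype-prediction architecture needs:
same-padded 1D cross-correlation, ReLU, max-pooling (window 2, stride 2),
flatten, inverted dropout, a dense layer, elementwise L1+L2 kernel penalties,
Adam, and an MAE training loop with early stopping that restores the weights
of the best validation epoch.

Conventions
-----------
* Activations are ``float32`` arrays shaped ``(batch, length, channels)``
  until flattened.
* Convolution is cross-correlation (no kernel flip), zero-padded so the
  output length equals the input length ("same" padding, odd kernels only).
* Kernels are initialised from a scaled normal with variance ``1/fan_in``
  (LeCun-style); biases start at zero.
* Dropout uses inverted scaling (kept units divided by the keep rate), so
  inference needs no rescaling and is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv1d_same",
    "relu",
    "Conv1DSame",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dropout",
    "Dense",
    "Network",
    "Adam",
    "fit_mae",
]


def relu(y: np.ndarray) -> np.ndarray:
    """Elementwise max(0, y)."""
    return np.maximum(0, y)


def _windows(x_pad: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows over axis 1: (B, Lp, C) -> (B, Lp-k+1, k, C)."""
    w = np.lib.stride_tricks.sliding_window_view(x_pad, k, axis=1)
    return np.ascontiguousarray(np.moveaxis(w, -1, 2))


def conv1d_same(X: np.ndarray, F: np.ndarray, B: np.ndarray | float = 0.0) -> np.ndarray:
    """Same-padded 1D cross-correlation ``Y = F * X + B``.

    Parameters
    ----------
    X : (L, C_in) or (batch, L, C_in)
    F : (k, C_in, C_out) filter bank, k odd
    B : (C_out,) bias (broadcastable)

    Returns an array of the same leading shape with C_out channels:
    ``Y[..., t, o] = sum_{d, i} X[..., t + d - (k-1)//2, i] * F[d, i, o] + B[o]``
    with zero padding at the borders.
    """
    X = np.asarray(X)
    F = np.asarray(F)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    if X.ndim != 3 or F.ndim != 3:
        raise ValueError("X must be (batch, L, C_in) and F (k, C_in, C_out)")
    k, c_in, c_out = F.shape
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    if X.shape[2] != c_in:
        raise ValueError(
            f"channel mismatch: X has {X.shape[2]} channels, F expects {c_in}"
        )
    pad = (k - 1) // 2
    x_pad = np.pad(X, ((0, 0), (pad, pad), (0, 0)))
    win = _windows(x_pad, k)  # (B, L, k, C_in)
    b, L = win.shape[0], win.shape[1]
    y = win.reshape(b * L, k * c_in) @ F.reshape(k * c_in, c_out)
    y = y.reshape(b, L, c_out) + np.asarray(B)
    return y[0] if squeeze else y


class Layer:
    """Base layer: parameter list plus forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def reg_penalty(self) -> float:
        return 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1DSame(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        l1: float = 0.0,
        l2: float = 0.0,
    ) -> None:
        super().__init__()
        fan_in = kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(kernel, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.l1, self.l2 = float(l1), float(l2)
        self.kernel = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.kernel
        pad = (k - 1) // 2
        x_pad = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._win = _windows(x_pad, k)  # (B, L, k, C_in)
        b, L = self._win.shape[0], self._win.shape[1]
        y = self._win.reshape(b * L, -1) @ self.W.reshape(-1, self.W.shape[2])
        return y.reshape(b, L, -1) + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, c_in, c_out = self.W.shape
        b, L = gy.shape[0], gy.shape[1]
        gy2 = gy.reshape(b * L, c_out)
        gW = (self._win.reshape(b * L, k * c_in).T @ gy2).reshape(k, c_in, c_out)
        gW += self.l1 * np.sign(self.W) + 2.0 * self.l2 * self.W
        self.grads[0][...] = gW
        self.grads[1][...] = gy2.sum(axis=0)
        # grad wrt input: full correlation of gy with the flipped, transposed bank
        pad = (k - 1) // 2
        gy_pad = np.pad(gy, ((0, 0), (pad, pad), (0, 0)))
        win = _windows(gy_pad, k)  # (B, L, k, C_out)
        Wt = self.W[::-1].transpose(0, 2, 1)  # (k, C_out, C_in), kernel flipped
        gx = win.reshape(b * L, k * c_out) @ Wt.reshape(k * c_out, c_in)
        self._win = None
        return gx.reshape(b, L, c_in)

    def reg_penalty(self) -> float:
        return float(self.l1 * np.abs(self.W).sum() + self.l2 * (self.W**2).sum())


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool1D(Layer):
    """Window-2, stride-2 max pool; output length floor(L/2)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, L, c = x.shape
        L2 = L // 2
        xt = x[:, : 2 * L2].reshape(b, L2, 2, c)
        self._arg = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, L2, c = gy.shape
        gx_pairs = np.zeros((b, L2, 2, c), dtype=gy.dtype)
        bi, li, ci = np.ogrid[:b, :L2, :c]
        gx_pairs[bi, li, self._arg, ci] = gy
        gx = np.zeros(self._in_shape, dtype=gy.dtype)
        gx[:, : 2 * L2] = gx_pairs.reshape(b, 2 * L2, c)
        self._arg = None
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        l1: float = 0.0,
        l2: float = 0.0,
    ) -> None:
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.l1, self.l2 = float(l1), float(l2)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ gy + self.l1 * np.sign(self.W) + 2.0 * self.l2 * self.W
        self.grads[1][...] = gy.sum(axis=0)
        gx = gy @ self.W.T
        self._x = None
        return gx

    def reg_penalty(self) -> float:
        return float(self.l1 * np.abs(self.W).sum() + self.l2 * (self.W**2).sum())


class Network:
    """A plain layer stack mapping (batch, L, C) to a (batch,) regression output."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h[:, 0]

    def backward(self, gout: np.ndarray) -> None:
        g = gout[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def reg_penalty(self) -> float:
        return sum(layer.reg_penalty() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adam with bias correction (Keras-style epsilon)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def fit_mae(
    net: Network,
    optimizer: Adam,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    max_epochs: int = 150,
    batch_size: int = 32,
    patience: int = 10,
    rng: np.random.Generator,
) -> dict:
    """Minimise MAE (+ kernel penalties) with early stopping on validation MAE.

    Returns a history dict with per-epoch ``train_mae`` / ``val_mae`` (pure
    MAE, penalty excluded), the ``best_epoch`` (1-based) and ``best_val_mae``.
    The network is left holding the best-epoch weights.
    """
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    n = X_train.shape[0]
    history: dict = {"train_mae": [], "val_mae": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    wait = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        abs_err_sum = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X_train[idx], y_train[idx]
            pred = net.forward(xb, training=True)
            resid = pred - yb
            loss = np.abs(resid).mean()
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting at {start})"
                )
            abs_err_sum += np.abs(resid).sum()
            net.backward(np.sign(resid) / len(idx))
            optimizer.step(net.grads)
        val_pred = net.forward(X_val, training=False)
        val_mae = float(np.abs(val_pred - y_val).mean())
        if not np.isfinite(val_mae):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history["train_mae"].append(float(abs_err_sum / n))
        history["val_mae"].append(val_mae)
        if val_mae < best_val:
            best_val = val_mae
            best_weights = net.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_mae"] = float(best_val)
    return history
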