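"""Lightweight five-block convolutional classifier for retinal-detachment grading.

The architecture is deliberately small: five convolutional blocks
(convolution -> batch normalization -> ReLU -> 2x2 stride-2 max pooling) with
a progressive filter count 8 -> 16 -> 32 -> 64 -> 128, a 512-unit fully
connected layer, 30% dropout, and a 4-way softmax head (classes ERD, Healthy,
RRD, TRD).  The first convolution uses a 3x3 kernel; the remaining four use
1x1 kernels (a ``conv_kernel="text"`` switch makes all five 3x3).

Everything — forward pass, backpropagation, stochastic gradient descent with
classical momentum and L2 weight decay — is implemented directly in numpy,
so training is exactly reproducible bit-for-bit given a seed on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    name = "layer"
    trainable: bool = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv2D(Layer):
    """Same-padding, stride-1 convolution in NHWC layout.

    1x1 kernels reduce to a channel-mixing matrix product; kxk kernels use an
    im2col matrix product.  He-normal weight initialization.
    """

    trainable = True

    def __init__(self, kernel: int, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.k = kernel
        self.cin = cin
        self.cout = cout
        self.name = name
        fan_in = kernel * kernel * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, cin, cout))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        n, h, w, _ = x.shape
        if self.k == 1:
            y = x @ self.W.reshape(self.cin, self.cout) + self.b
            return y
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (n, h, w, k, k, cin)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)
        self._cols = cols.reshape(n * h * w, -1)
        wmat = self.W.transpose(0, 1, 2, 3).reshape(-1, self.cout)
        y = self._cols @ wmat + self.b
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy):
        x = self._x
        n, h, w, _ = x.shape
        dymat = dy.reshape(-1, self.cout)
        self.db = dymat.sum(axis=0)
        if self.k == 1:
            self.dW = (x.reshape(-1, self.cin).T @ dymat).reshape(self.W.shape)
            return (dymat @ self.W.reshape(self.cin, self.cout).T).reshape(x.shape)
        self.dW = (self._cols.T @ dymat).reshape(self.W.shape)
        dcols = (dymat @ self.W.reshape(-1, self.cout).T).reshape(n, h, w, self.k, self.k, self.cin)
        pad = self.k // 2
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.cin))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, pad:pad + h, pad:pad + w, :]

    def params(self):
        return [
            {"name": f"{self.name}.W", "value": self.W, "grad": lambda: self.dW, "decay": True},
            {"name": f"{self.name}.b", "value": self.b, "grad": lambda: self.db, "decay": False},
        ]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    trainable = True

    def __init__(self, channels: int, name: str, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma * self._istd
        m = self._m
        dxhat = dy * self.gamma
        return (self._istd / m) * (
            m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )

    def params(self):
        return [
            {"name": f"{self.name}.gamma", "value": self.gamma, "grad": lambda: self.dgamma, "decay": False},
            {"name": f"{self.name}.beta", "value": self.beta, "grad": lambda: self.dbeta, "decay": False},
        ]


class ReLU(Layer):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; ties resolved to the first maximum."""

    def __init__(self, name: str):
        self.name = name

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        xw = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = xw.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xw, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dwin.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx


class Flatten(Layer):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.name = name
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [
            {"name": f"{self.name}.W", "value": self.W, "grad": lambda: self.dW, "decay": True},
            {"name": f"{self.name}.b", "value": self.b, "grad": lambda: self.db, "decay": False},
        ]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.name = name

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture description of the five-block classifier."""

    input_size: int = 224
    in_channels: int = 3
    filters: tuple[int, ...] = (8, 16, 32, 64, 128)
    conv_kernel: str = "table"  # "table": 3x3 then 1x1; "text": 3x3 throughout
    dense_units: int = 512
    dropout: float = 0.30
    n_classes: int = 4

    def kernel_for_block(self, block: int) -> int:
        if self.conv_kernel == "table":
            return 3 if block == 0 else 1
        if self.conv_kernel == "text":
            return 3
        raise ValueError(f"conv_kernel must be 'table' or 'text', got {self.conv_kernel!r}")


class Network:
    """Plain feed-forward stack of layers ending in 4 logits (softmax applied
    separately), with enough bookkeeping for Grad-CAM backprojection."""

    def __init__(self, layers: list[Layer], config: NetworkConfig, rng: np.random.Generator):
        self.layers = layers
        self.config = config
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate from the logits; returns the gradient flowing into
        layer ``stop_at`` (i.e. w.r.t. the output of layer ``stop_at - 1``)."""
        dy = dlogits
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference forward pass returning every layer's output (for Grad-CAM)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            outs.append(x)
        return outs

    def layer_index(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise KeyError(name)

    def shape_trace(self, input_size: int | None = None) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes for a single input image (no batch axis)."""
        size = input_size or self.config.input_size
        x = np.zeros((1, size, size, self.config.in_channels))
        trace = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            trace.append((layer.name, tuple(x.shape[1:])))
        return trace

    def parameters(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> Network:
    """Construct the five-block network with deterministic He initialization."""
    cfg = cfg or NetworkConfig()
    if tuple(cfg.filters) != (8, 16, 32, 64, 128):
        raise ValueError("filter progression must be 8->16->32->64->128")
    if cfg.input_size % 32 != 0 and cfg.input_size != 224:
        raise ValueError("input size must be divisible by 32 (or the canonical 224)")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    cin = cfg.in_channels
    size = cfg.input_size
    for i, cout in enumerate(cfg.filters):
        k = cfg.kernel_for_block(i)
        layers.append(Conv2D(k, cin, cout, rng, name=f"conv{i + 1}"))
        layers.append(BatchNorm(cout, name=f"bn{i + 1}"))
        layers.append(ReLU(name=f"relu{i + 1}"))
        layers.append(MaxPool2(name=f"pool{i + 1}"))
        cin = cout
        size //= 2
    layers.append(Flatten(name="flatten"))
    layers.append(Dense(size * size * cfg.filters[-1], cfg.dense_units, rng, name="fc1"))
    layers.append(Dropout(cfg.dropout, rng, name="dropout"))
    layers.append(Dense(cfg.dense_units, cfg.n_classes, rng, name="fc2"))
    return Network(layers, cfg, rng)


def count_parameters(net: Network) -> int:
    """Exact count of trainable scalars (conv/dense weights and biases,
    batch-norm scale and shift)."""
    return sum(p["value"].size for p in net.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_proba(net: Network, x: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch (or a single image); dropout inactive."""
    single = x.ndim == 3
    if single:
        x = x[None]
    expected = (net.config.input_size, net.config.input_size, net.config.in_channels)
    if x.shape[1:] != expected:
        raise ValueError(f"expected input shape {expected}, got {x.shape[1:]}")
    p = softmax(net.forward(x, training=False))
    return p[0] if single else p


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class Hyperparams:
    """Tunable training knobs.  Defaults are the grey-wolf-optimized values
    (momentum 0.949, learning rate 0.00497, L2 coefficient 0.0029); the epoch
    budget defaults to 30."""

    momentum: float = 0.949
    learning_rate: float = 0.00497
    epochs: int = 30
    l2: float = 0.0029

    def __post_init__(self):
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    seed: int = 0


def recalibrate_batchnorm(net: Network, x: np.ndarray, batch: int = 64) -> None:
    """Replace every batch-norm layer's running statistics with exact
    population moments over ``x``.

    After very short training runs the exponentially averaged statistics lag
    the weights badly enough to hurt inference accuracy; one deterministic
    pass fixes them.  Layers are processed front to back so each layer's
    moments are computed with the finalized statistics of the layers before
    it.
    """
    bn_idx = [i for i, layer in enumerate(net.layers) if isinstance(layer, BatchNorm)]
    for bi in bn_idx:
        total = None
        total_sq = None
        count = 0
        for start in range(0, len(x), batch):
            a = x[start:start + batch]
            for layer in net.layers[:bi]:
                a = layer.forward(a, training=False)
            axes = tuple(range(a.ndim - 1))
            s = a.sum(axis=axes)
            sq = (a**2).sum(axis=axes)
            total = s if total is None else total + s
            total_sq = sq if total_sq is None else total_sq + sq
            count += a.size // a.shape[-1]
        mean = total / count
        layer_bn = net.layers[bi]
        layer_bn.running_mean = mean
        layer_bn.running_var = np.maximum(total_sq / count - mean**2, 0.0)


def _batch_accuracy(net: Network, x: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
    correct = 0
    for i in range(0, len(x), batch):
        p = net.forward(x[i:i + batch], training=False)
        correct += int((p.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / len(x)


def train(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    hp: Hyperparams | None = None,
    seed: int = 0,
    batch_size: int = 32,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainingHistory:
    """Mini-batch SGD with classical momentum, L2 weight decay and
    cross-entropy loss.  ``y`` holds integer class indices.

    The run is fully reproducible: shuffling and dropout both derive from
    ``seed``.
    """
    hp = hp or Hyperparams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    rng = np.random.default_rng(seed)
    net.rng = rng
    for layer in net.layers:
        if isinstance(layer, Dropout):
            layer.rng = rng
    params = net.parameters()
    velocity = [np.zeros_like(p["value"]) for p in params]
    history = TrainingHistory(seed=seed)
    n = len(x)
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb, training=True)
            p = softmax(logits)
            epoch_loss += float(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-12)).sum())
            epoch_correct += int((p.argmax(axis=1) == yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            net.backward(dlogits)
            for pdict, v in zip(params, velocity):
                g = pdict["grad"]()
                if pdict["decay"]:
                    g = g + hp.l2 * pdict["value"]
                v *= hp.momentum
                v -= hp.learning_rate * g
                pdict["value"] += v
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_correct / n)
        if x_val is not None and len(x_val):
            history.val_accuracy.append(_batch_accuracy(net, x_val, y_val))
    if hp.epochs > 0:
        recalibrate_batchnorm(net, x)
    return history


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class LightMGNet(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier wrapping the numpy network.

    ``X`` is an (n, H, W, 3) array of images on the 0-255 scale (H = W =
    ``input_size``); ``y`` holds class labels.  Pixel values are rescaled to
    [0, 1] internally.

    Parameters mirror the tuned training configuration: SGD momentum,
    learning rate, epoch budget and L2 coefficient, plus the architecture
    switches (input size, conv-kernel variant, dropout rate).
    """

    def __init__(
        self,
        input_size: int = 64,
        conv_kernel: str = "table",
        dense_units: int = 512,
        dropout: float = 0.30,
        momentum: float = 0.949,
        learning_rate: float = 0.00497,
        epochs: int = 30,
        l2: float = 0.0029,
        batch_size: int = 32,
        validation_fraction: float = 0.0,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.conv_kernel = conv_kernel
        self.dense_units = dense_units
        self.dropout = dropout
        self.momentum = momentum
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.l2 = l2
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self, n_classes: int = 4) -> NetworkConfig:
        return NetworkConfig(
            input_size=self.input_size,
            conv_kernel=self.conv_kernel,
            dense_units=self.dense_units,
            dropout=self.dropout,
            n_classes=n_classes,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64) / 255.0
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1:] != (self.input_size, self.input_size, 3):
            raise ValueError(
                f"X must have shape (n, {self.input_size}, {self.input_size}, 3), got {X.shape}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        x_val = y_val = None
        if self.validation_fraction > 0:
            X, x_val, y_idx, y_val = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=self.random_state,
            )
        self.network_ = build_network(self._config(len(self.classes_)), seed=self.random_state)
        self.history_ = train(
            self.network_, X, y_idx,
            Hyperparams(self.momentum, self.learning_rate, self.epochs, self.l2),
            seed=self.random_state, batch_size=self.batch_size,
            x_val=x_val, y_val=y_val,
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float64) / 255.0
        out = []
        for i in range(0, len(X), 64):
            out.append(predict_proba(self.network_, X[i:i + 64]))
        return np.concatenate(out) if out else np.empty((0, len(self.classes_)))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
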