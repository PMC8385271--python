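"""Compact NumPy CNN for spectrogram classification.

Architecture (fixed by design, sized for 31 x 56 inputs): three blocks of
3 x 3 same-padded stride-1 convolution -> batch normalization -> ReLU with
16, 32 and 64 channels (feature maps stay 31 x 56 throughout — no pooling),
then flatten -> fully connected 128 -> ReLU -> fully connected 2 -> softmax.
Training minimizes the binary cross-entropy
``L = -[y log p + (1 - y) log(1 - p)]`` by mini-batch Adam.

Convolutions run as im2col matrix products; gradients are analytic (the
input gradient is the full correlation of the output gradient with the
180-degree-rotated, channel-transposed kernels) and are verified against
numerical differentiation in the test suite. All forward/backward math is
vectorized float32 by default; float64 is available for gradient checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "SpectrogramCNN",
    "build_cnn",
    "cross_entropy",
    "train_cnn",
]

EPS_PROB = 1e-7  # probability clipping inside the loss


@dataclass(frozen=True)
class CnnSpec:
    input_shape: tuple[int, int] = (31, 56)
    conv_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    fc_units: int = 128
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        if len(self.input_shape) != 2 or any(s <= 0 for s in self.input_shape):
            raise ValueError("input_shape must be two positive integers")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "conv_channels": list(self.conv_channels),
            "kernel_size": self.kernel_size,
            "fc_units": self.fc_units,
            "n_classes": self.n_classes,
        }


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def cross_entropy(y: np.ndarray, p: np.ndarray, eps: float = EPS_PROB) -> np.ndarray:
    """Binary cross-entropy on clipped probabilities; vectorized in y, p."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


# ---------------------------------------------------------------------------
# layers — each exposes forward(x, training) and backward(dy), with params /
# grads stored as lists so the optimizer can walk them uniformly


class _Conv2DSame:
    """3x3 (odd k) same-padded stride-1 convolution.

    Implemented as one GEMM per kernel offset on shifted views of the padded
    input (equivalent to im2col but without materialising the k*k-fold
    patch matrix): y = sum_{a,b} shift(x, a, b) @ W[a, b].
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype):
        fan_in = k * k * c_in
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = rng.standard_normal((k, k, c_in, c_out), dtype=dtype)
        self.W *= np.sqrt(2.0 / fan_in)  # He initialisation
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        bsz, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        y = np.zeros((bsz * h * w, self.c_out), dtype=x.dtype)
        for a in range(k):
            for bb in range(k):
                xs = xp[:, a : a + h, bb : bb + w, :].reshape(-1, self.c_in)
                y += xs @ self.W[a, bb]
        y += self.b
        if training:
            self._xp = xp
            self._hw = (h, w)
        return y.reshape(bsz, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        bsz, h, w, _ = dy.shape
        dflat = dy.reshape(-1, self.c_out)
        self.grads[1][...] = dflat.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for bb in range(k):
                xs = self._xp[:, a : a + h, bb : bb + w, :].reshape(-1, self.c_in)
                self.grads[0][a, bb] = xs.T @ dflat
                dxp[:, a : a + h, bb : bb + w, :] += (dflat @ self.W[a, bb].T).reshape(
                    bsz, h, w, self.c_in
                )
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :]


class _BatchNorm:
    """Per-channel batch normalization over (B, H, W); running stats at eval."""

    def __init__(self, c: int, dtype, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        m = dy.size // dy.shape[-1]
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes) / m
        ) / self._std
        self._xhat = None
        return dx


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype):
        self.W = rng.standard_normal((n_in, n_out), dtype=dtype)
        self.W *= np.sqrt(2.0 / n_in)  # He initialisation
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] = self._x.T @ dy
        self.grads[1] = dy.sum(axis=0)
        dx = (self.W @ dy.T).T
        self._x = None
        return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SpectrogramCNN:
    """The spectrogram classifier; seeded construction is fully deterministic."""

    def __init__(self, spec: CnnSpec | None = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or CnnSpec()
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        s = self.spec
        layers: list = []
        c_in = 1
        for c_out in s.conv_channels:
            layers.append(_Conv2DSame(c_in, c_out, s.kernel_size, rng, self.dtype))
            layers.append(_BatchNorm(c_out, self.dtype))
            layers.append(_ReLU())
            c_in = c_out
        layers.append(_Flatten())
        flat = s.input_shape[0] * s.input_shape[1] * c_in
        layers.append(_Dense(flat, s.fc_units, rng, self.dtype))
        layers.append(_ReLU())
        layers.append(_Dense(s.fc_units, s.n_classes, rng, self.dtype))
        self.layers = layers

    # -- plumbing ----------------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim == 3:
            X = X[..., None]
        if X.shape[1:3] != self.spec.input_shape or X.shape[3] != 1:
            raise ValueError(
                f"expected inputs of shape {self.spec.input_shape} (+1 channel), "
                f"got {X.shape[1:]}"
            )
        return X

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities (softmax outputs), shape (B, n_classes)."""
        h = self._check_input(X)
        for layer in self.layers:
            h = layer.forward(h, training)
        return _softmax(h.astype(np.float64))

    def intermediate_shapes(self, X: np.ndarray) -> list[tuple[int, ...]]:
        """Feature-map shapes after each conv block (diagnostic)."""
        h = self._check_input(X)
        shapes = []
        for layer in self.layers:
            h = layer.forward(h, training=False)
            if isinstance(layer, _ReLU) and h.ndim == 4:
                shapes.append(h.shape[1:])
        return shapes

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; fills parameter gradients."""
        y = np.asarray(y, dtype=int)
        probs = self.forward(X, training=True)
        p1 = probs[:, 1]
        loss = float(np.mean(cross_entropy(y, p1)))
        # d(mean CE)/d(logits) with clipping ignored (active only at saturation)
        onehot = np.eye(self.spec.n_classes)[y]
        dlogits = ((probs - onehot) / len(y)).astype(self.dtype)
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Batch-norm uses frozen running statistics (inference mode)."""
        X = np.asarray(X)
        out = [
            self.forward(X[i : i + batch_size], training=False)
            for i in range(0, len(X), batch_size)
        ]
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def build_cnn(spec: CnnSpec | None = None, seed: int = 0, dtype=np.float32) -> SpectrogramCNN:
    return SpectrogramCNN(spec, seed=seed, dtype=dtype)


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self._scratch = np.empty(max(p.size for p in params), dtype=params[0].dtype)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        # in-place throughout; the largest parameter dominates memory traffic
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            buf = self._scratch[: p.size].reshape(p.shape)
            m *= c.beta1
            np.multiply(g, 1.0 - c.beta1, out=buf)
            m += buf
            v *= c.beta2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - c.beta2
            v += buf
            np.divide(v, b2t, out=buf)
            np.sqrt(buf, out=buf)
            buf += c.adam_eps
            np.divide(m, buf, out=buf)
            buf *= c.learning_rate / b1t
            p -= buf


def train_cnn(
    model: SpectrogramCNN,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> dict:
    """Mini-batch Adam on the cross-entropy loss; returns the loss trace.

    The epoch shuffle order is drawn from ``cfg.seed``, so training is
    reproducible end to end for a fixed model seed and config.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters, cfg)
    trace = []
    n = len(y)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = model.loss_and_grad(X[idx], y[idx])
            opt.step(model.parameters, model.gradients)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    _reestimate_bn_stats(model, X, cfg.batch_size)
    return {"loss_trace": trace, "epochs": cfg.epochs}


def _reestimate_bn_stats(
    model: SpectrogramCNN, X: np.ndarray, batch_size: int, max_examples: int = 128
) -> None:
    """Set batch-norm running statistics from a pass over the training set.

    With short training runs the exponential running averages never leave
    their initialisation, which would make frozen-statistics inference
    meaningless; a final estimate under the trained weights fixes that while
    keeping prediction-time statistics frozen. Statistics are pooled over at
    most ``max_examples`` training images (each image already contributes
    height x width samples per channel, so this is plenty).
    """
    if len(X) > max_examples:
        X = X[:: int(np.ceil(len(X) / max_examples))]
    bns = [l for l in model.layers if isinstance(l, _BatchNorm)]
    sums = [None] * len(bns)
    for start in range(0, len(X), batch_size):
        h = model._check_input(X[start : start + batch_size])
        j = 0
        for layer in model.layers:
            if isinstance(layer, _BatchNorm):
                axes = tuple(range(h.ndim - 1))
                mu = h.mean(axis=axes)
                var = h.var(axis=axes)
                w = h.size // h.shape[-1]
                if sums[j] is None:
                    sums[j] = [mu * w, var * w, w]
                else:
                    sums[j][0] += mu * w
                    sums[j][1] += var * w
                    sums[j][2] += w
                # normalise this batch with its own stats, as during training
                h = layer.gamma * (h - mu) / np.sqrt(var + layer.eps) + layer.beta
                j += 1
            else:
                h = layer.forward(h, training=False)
            if j == len(bns) and not isinstance(layer, _BatchNorm):
                break
    for layer, s in zip(bns, sums):
        layer.running_mean = s[0] / s[2]
        layer.running_var = s[1] / s[2]
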