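"""Minimal convolutional backbone in numpy.

A small CNN (conv / batch-norm / ReLU blocks, global average pooling, and a
single-logit linear head) with hand-written backpropagation and an Adam
optimizer.  The design goal is not speed records but a fully deterministic,
dependency-free backbone exposing *named, kind-tagged parameters* so the
partial fine-tuning contract — train only the batch-norm affine parameters
and the final classification layer, freeze everything else — can be
enforced and verified bit-exactly.

Parameter kinds: ``conv_weight``, ``conv_bias``, ``norm_scale``,
``norm_shift``, ``head_weight``, ``head_bias``.  Batch-norm running
statistics are buffers, not parameters.

Inputs are NCHW float arrays; tiles are fed as gray values rescaled to
[-0.5, 0.5].  Training mode uses batch statistics in the norm layers;
evaluation mode uses running statistics, which makes inference independent
of batch composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class Parameter:
    name: str
    kind: str
    value: np.ndarray
    trainable: bool = True
    grad: np.ndarray | None = field(default=None, repr=False)


class _Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(_Layer):
    """3x3 convolution, padding 1, configurable stride, NCHW."""

    def __init__(self, name, cin, cout, stride, rng):
        k = 3
        self.k, self.stride = k, stride
        scale = np.sqrt(2.0 / (cin * k * k))  # He init
        self.weight = Parameter(f"{name}.weight", "conv_weight", scale * rng.standard_normal((cout, cin, k, k)))
        self.bias = Parameter(f"{name}.bias", "conv_bias", np.zeros(cout))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def _windows(self, x):
        k, s = self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        return xp.shape, win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)

    def forward(self, x, training):
        pshape, win = self._windows(x)
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = cols @ wmat.T + self.bias.value
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if training:
            self._cache = (x.shape, pshape, cols, (n, ho, wo))
        return out

    def backward(self, dout):
        xshape, pshape, cols, (n, ho, wo) = self._cache
        cout = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        self.weight.grad = (dmat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad = dmat.sum(axis=0)
        k, s = self.k, self.stride
        cin = xshape[1]
        # scatter gradient back through the windows: one strided add per tap
        dcols = (dmat @ self.weight.value.reshape(cout, -1)).reshape(n, ho, wo, cin, k, k)
        dxp = np.zeros(pshape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2d(_Layer):
    """Per-channel batch normalization with affine scale/shift."""

    def __init__(self, name, c):
        self.scale = Parameter(f"{name}.scale", "norm_scale", np.ones(c))
        self.shift = Parameter(f"{name}.shift", "norm_shift", np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.name = name
        self._cache = None

    def parameters(self):
        return [self.scale, self.shift]

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean, f"{self.name}.running_var": self.running_var}

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += _BN_MOMENTUM * (mean - self.running_mean)
            self.running_var += _BN_MOMENTUM * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.scale.value[None, :, None, None] * xhat + self.shift.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.scale.grad = (dout * xhat).sum(axis=(0, 2, 3))
        self.shift.grad = dout.sum(axis=(0, 2, 3))
        g = self.scale.value[None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx


class ReLU(_Layer):
    def forward(self, x, training):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(_Layer):
    def __init__(self, name, cin, cout, rng):
        scale = np.sqrt(1.0 / cin)
        self.weight = Parameter(f"{name}.weight", "head_weight", scale * rng.standard_normal((cout, cin)))
        self.bias = Parameter(f"{name}.bias", "head_bias", np.zeros(cout))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad = dout.T @ self._x
        self.bias.grad = dout.sum(axis=0)
        return dout @ self.weight.value


class TinyCNN:
    """Three stride-2 conv/BN/ReLU blocks, global pooling, single-logit head.

    Accepts any input size >= 8 px; with 128-px tiles the feature map sizes
    are 64, 32 and 16 px.  ``width`` scales the channel counts.
    """

    def __init__(self, in_channels: int = 1, width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [in_channels, width, 2 * width, 4 * width]
        self.layers: list[_Layer] = []
        for i in range(3):
            self.layers.append(Conv2d(f"block{i}.conv", chans[i], chans[i + 1], 2, rng))
            self.layers.append(BatchNorm2d(f"block{i}.norm", chans[i + 1]))
            self.layers.append(ReLU())
        self.layers.append(GlobalAvgPool())
        self.layers.append(Linear("head", chans[-1], 1, rng))
        self.config = {"in_channels": in_channels, "width": width, "seed": seed}

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            out.update(layer.buffers())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        state.update({k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                layer.running_var[...] = state[f"{layer.name}.running_var"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Return the logit per sample, shape (N,)."""
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Positive-class probability in eval mode (running BN statistics)."""
        return sigmoid(self.forward(x, training=False))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(self.config))

    @classmethod
    def load(cls, path: str | Path) -> "TinyCNN":
        path = Path(path)
        config = json.loads(path.with_suffix(".json").read_text())
        model = cls(**config)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict(dict(data))
        return model


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(prob: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    """Adam over the trainable parameters of a model."""

    def __init__(self, params: list[Parameter], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable or p.grad is None:
                continue
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
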