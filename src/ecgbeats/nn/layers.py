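"""Trainable layers with explicit forward/backward passes.

All layers operate on float64 batches. 1-D sequence tensors are shaped
``(batch, time, channels)``; flat tensors are ``(batch, features)``.
Each layer stores its parameters in ``self.params`` (name -> ndarray) and
accumulates gradients of the batch loss in ``self.grads`` under the same keys.
``backward`` consumes the gradient w.r.t. the layer output and returns the
gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as _sigmoid

__all__ = [
    "Layer",
    "SeparableConv1D",
    "BatchNorm",
    "MaxPool1D",
    "BiLSTM",
    "Flatten",
    "Dropout",
    "Dense",
]


def _activation(name):
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0),
                lambda z, a: (z > 0.0).astype(z.dtype))
    if name == "elu":
        return (lambda z: np.where(z > 0.0, z, np.expm1(z)),
                lambda z, a: np.where(z > 0.0, 1.0, a + 1.0))
    if name == "linear":
        return (lambda z: z, lambda z, a: np.ones_like(z))
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameter bookkeeping shared by all layers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.non_trainable: dict[str, np.ndarray] = {}

    @property
    def n_params(self) -> int:
        return self.n_trainable + self.n_non_trainable

    @property
    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def n_non_trainable(self) -> int:
        return int(sum(p.size for p in self.non_trainable.values()))

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class SeparableConv1D(Layer):
    """Depthwise-separable 1-D convolution, valid padding, stride 1.

    A per-channel temporal filter (depthwise, no bias) followed by a 1x1
    pointwise channel mixer with bias, then the activation.  Parameter count is
    ``k*c_in + c_in*c_out + c_out``.
    """

    def __init__(self, c_in, c_out, kernel=3, activation="relu", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel = int(kernel)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.act, self.dact = _activation(activation)
        self.params = {
            "depthwise": _glorot(rng, (kernel, c_in), kernel * c_in, c_in),
            "pointwise": _glorot(rng, (c_in, c_out), c_in, c_out),
            "bias": np.zeros(c_out),
        }
        self.zero_grads()

    def out_length(self, t_in: int) -> int:
        return t_in - self.kernel + 1

    def forward(self, x, training=False):
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel}")
        win = sliding_window_view(x, self.kernel, axis=1)  # (B, To, C, k)
        depth = np.einsum("btck,kc->btc", win, self.params["depthwise"])
        z = depth @ self.params["pointwise"] + self.params["bias"]
        a = self.act(z)
        self._cache = (x, win, depth, z, a)
        return a

    def backward(self, grad):
        x, win, depth, z, a = self._cache
        gz = grad * self.dact(z, a)
        self.grads["pointwise"] += np.einsum("btc,bto->co", depth, gz)
        self.grads["bias"] += gz.sum(axis=(0, 1))
        gdepth = gz @ self.params["pointwise"].T
        self.grads["depthwise"] += np.einsum("btck,btc->kc", win, gdepth)
        gx = np.zeros_like(x)
        to = gdepth.shape[1]
        wd = self.params["depthwise"]
        for j in range(self.kernel):
            gx[:, j:j + to, :] += gdepth * wd[j][None, None, :]
        return gx


class BatchNorm(Layer):
    """Batch normalization over the channel axis (last axis).

    For 3-D input the statistics pool over batch and time.  gamma/beta are
    trainable; the moving mean/variance (2 per channel) are the non-trainable
    parameters.  The moving-average momentum defaults to 0.9 so the inference
    statistics converge within the few hundred batches a typical run here
    sees; epsilon is 1e-3.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.non_trainable = {
            "moving_mean": np.zeros(channels),
            "moving_var": np.ones(channels),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.non_trainable["moving_mean"] *= m
            self.non_trainable["moving_mean"] += (1 - m) * mu
            self.non_trainable["moving_var"] *= m
            self.non_trainable["moving_var"] += (1 - m) * var
        else:
            mu = self.non_trainable["moving_mean"]
            var = self.non_trainable["moving_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (x, mu, std, xhat, axes)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        x, mu, std, xhat, axes = self._cache
        self.grads["gamma"] += (grad * xhat).sum(axis=axes)
        self.grads["beta"] += grad.sum(axis=axes)
        gxhat = grad * self.params["gamma"]
        # backprop through the batch statistics, in the usual reduced form:
        # gx = (gxhat - mean(gxhat) - xhat * mean(gxhat * xhat)) / std
        return (gxhat - gxhat.mean(axis=axes)
                - xhat * (gxhat * xhat).mean(axis=axes)) / std


class MaxPool1D(Layer):
    """Temporal max pooling, size 2 / stride 2; an odd trailing step is dropped."""

    def __init__(self, size=2, stride=2):
        super().__init__()
        if size != stride:
            raise ValueError("only size == stride pooling is supported")
        self.size = int(size)

    def out_length(self, t_in: int) -> int:
        return t_in // self.size

    def forward(self, x, training=False):
        b, t, c = x.shape
        to = t // self.size
        blocks = x[:, : to * self.size, :].reshape(b, to, self.size, c)
        arg = blocks.argmax(axis=2)
        self._cache = (x.shape, arg)
        return blocks.max(axis=2)

    def backward(self, grad):
        shape, arg = self._cache
        b, t, c = shape
        to = arg.shape[1]
        gx = np.zeros(shape)
        blocks = gx[:, : to * self.size, :].reshape(b, to, self.size, c)
        np.put_along_axis(blocks, arg[:, :, None, :], grad[:, :, None, :],
                          axis=2)
        return gx


class _LSTMDirection:
    """One direction of an LSTM; gates ordered (input, forget, output, cell)
    so the three sigmoid gates occupy one contiguous block."""

    def __init__(self, d_in, units, rng):
        u = units
        self.units = u
        self.W = _glorot(rng, (d_in, 4 * u), d_in, 4 * u)
        self.U = _glorot(rng, (u, 4 * u), u, 4 * u)
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0  # forget-gate bias starts open
        self.zero_grads()

    def zero_grads(self):
        self.gW = np.zeros_like(self.W)
        self.gU = np.zeros_like(self.U)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u))
        c = np.zeros((b, u))
        cache = []
        xw = x @ self.W  # precompute input contribution for every step
        for step in range(t):
            z = xw[:, step, :] + h @ self.U + self.b
            gates = _sigmoid(z[:, :3 * u])
            i, f, o = gates[:, :u], gates[:, u:2 * u], gates[:, 2 * u:]
            g = np.tanh(z[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        self._cache = (x, cache)
        return h

    def backward(self, gh_final):
        x, cache = self._cache
        b, t, _ = x.shape
        u = self.units
        gh = gh_final.copy()
        gc = np.zeros((b, u))
        gx = np.zeros_like(x)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[step]
            go = gh * tc
            gc = gc + gh * o * (1.0 - tc * tc)
            gi, gf, gg = gc * g, gc * c_prev, gc * i
            gz = np.concatenate([
                gi * i * (1 - i),
                gf * f * (1 - f),
                go * o * (1 - o),
                gg * (1 - g * g),
            ], axis=1)
            self.gW += x[:, step, :].T @ gz
            self.gU += h_prev.T @ gz
            self.gb += gz.sum(axis=0)
            gx[:, step, :] = gz @ self.W.T
            gh = gz @ self.U.T
            gc = gc * f
        return gx


class BiLSTM(Layer):
    """Bidirectional LSTM emitting only the final step's concatenated state.

    Output is ``(batch, 2*units)``: the forward pass's state after the last
    time step next to the backward pass's state after the first.  Per
    direction the parameter count is ``4*(d*u + u*u + u)``.
    """

    def __init__(self, d_in, units, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = int(units)
        self.fwd = _LSTMDirection(d_in, units, rng)
        self.bwd = _LSTMDirection(d_in, units, rng)

    @property
    def n_trainable(self):
        return int(sum(a.size for d in (self.fwd, self.bwd)
                       for a in (d.W, d.U, d.b)))

    @property
    def n_non_trainable(self):
        return 0

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x, training=False):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, grad):
        u = self.units
        gx = self.fwd.backward(grad[:, :u])
        gx_b = self.bwd.backward(grad[:, u:])
        return gx + gx_b[:, ::-1, :]


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate, rng=None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    """Fully connected layer; supports relu/elu/linear/softmax activations."""

    def __init__(self, d_in, d_out, activation="linear", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.activation = activation
        if activation != "softmax":
            self.act, self.dact = _activation(activation)
        self.params = {
            "weight": _glorot(rng, (d_in, d_out), d_in, d_out),
            "bias": np.zeros(d_out),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        z = x @ self.params["weight"] + self.params["bias"]
        if self.activation == "softmax":
            zs = z - z.max(axis=1, keepdims=True)
            ez = np.exp(zs)
            a = ez / ez.sum(axis=1, keepdims=True)
        else:
            a = self.act(z)
        self._cache = (x, z, a)
        return a

    def backward(self, grad, grad_is_preactivation=False):
        x, z, a = self._cache
        if grad_is_preactivation:
            gz = grad
        elif self.activation == "softmax":
            # full softmax Jacobian product
            dot = (grad * a).sum(axis=1, keepdims=True)
            gz = a * (grad - dot)
        else:
            gz = grad * self.dact(z, a)
        self.grads["weight"] += x.T @ gz
        self.grads["bias"] += gz.sum(axis=0)
        return gz @ self.params["weight"].T
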