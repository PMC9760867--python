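"""Sequential network container used by the classifier."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, BiLSTM, Dense, Layer


class Network:
    """A plain sequential stack of layers with explicit backprop.

    The final layer is expected to be a softmax :class:`Dense`; training code
    passes the cross-entropy gradient w.r.t. the logits directly to
    :meth:`backward` with ``last_grad_is_preactivation=True``, which avoids
    materialising the softmax Jacobian.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray, last_grad_is_preactivation: bool = True):
        last = self.layers[-1]
        if isinstance(last, Dense):
            grad = last.backward(grad, grad_is_preactivation=last_grad_is_preactivation)
        else:
            grad = last.backward(grad)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def recalibrate_batchnorm(self, x: np.ndarray, batch_size: int = 512):
        """Replace batch-norm moving statistics with exact statistics of
        ``x`` (normally the training set).

        The exponential moving averages accumulated during training lag the
        final weights and are noisy when batches are small; this pass removes
        the train/inference discrepancy.  Each batch-norm layer's inputs are
        recomputed in inference mode (earlier layers already recalibrated),
        then its moving mean/variance are set to the full-dataset moments.
        """
        for target_idx, target in enumerate(self.layers):
            if not isinstance(target, BatchNorm):
                continue
            n_total = 0
            s = s2 = 0.0
            for lo in range(0, x.shape[0], batch_size):
                data = x[lo:lo + batch_size]
                for layer in self.layers[:target_idx]:
                    data = layer.forward(data, training=False)
                axes = tuple(range(data.ndim - 1))
                n_total += int(np.prod([data.shape[a] for a in axes]))
                s = s + data.sum(axis=axes)
                s2 = s2 + (data ** 2).sum(axis=axes)
            mean = s / n_total
            target.non_trainable["moving_mean"][...] = mean
            target.non_trainable["moving_var"][...] = s2 / n_total - mean ** 2

    def param_items(self):
        """Yield (unique_key, layer, param_key) for every trainable array."""
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BiLSTM):
                for direction, name in ((layer.fwd, "fwd"), (layer.bwd, "bwd")):
                    for pk in ("W", "U", "b"):
                        yield f"{i}.{name}.{pk}", direction, pk
            else:
                for pk in layer.params:
                    yield f"{i}.{pk}", layer, pk

    @staticmethod
    def get_param(owner, pk):
        if isinstance(owner, Layer):
            return owner.params[pk]
        return getattr(owner, pk)  # LSTM direction

    @staticmethod
    def get_grad(owner, pk):
        if isinstance(owner, Layer):
            return owner.grads[pk]
        return getattr(owner, "g" + pk)

    @property
    def n_trainable(self) -> int:
        return int(sum(l.n_trainable for l in self.layers))

    @property
    def n_non_trainable(self) -> int:
        return int(sum(l.n_non_trainable for l in self.layers))

    @property
    def n_params(self) -> int:
        return self.n_trainable + self.n_non_trainable

    def layer_param_counts(self) -> list[int]:
        return [l.n_params for l in self.layers]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for key, owner, pk in self.param_items():
            out[key] = self.get_param(owner, pk).copy()
        for i, layer in enumerate(self.layers):
            for nk, arr in layer.non_trainable.items():
                out[f"{i}.{nk}"] = arr.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]):
        for key, owner, pk in self.param_items():
            self.get_param(owner, pk)[...] = weights[key]
        for i, layer in enumerate(self.layers):
            for nk, arr in layer.non_trainable.items():
                arr[...] = weights[f"{i}.{nk}"]
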