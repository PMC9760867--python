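"""Architecture specification and construction of the separable-CNN + Bi-LSTM
heartbeat classifier.

The default network takes a 187-sample beat segment through three
depthwise-separable 1-D convolutions (valid padding, kernel 3, 32/64/128
filters), batch normalization, max-pooling (size 2, stride 2), a bidirectional
LSTM with 128 units per direction returning only the final concatenated state,
then dropout, a 512-unit dense layer, batch normalization and a 5-way softmax.
With these defaults it has 410,664 parameters (409,384 trainable, 1,280
non-trainable batch-norm moving statistics).

:func:`parameter_table` computes the per-layer parameter budget in closed
form; :func:`build_network` constructs the trainable network and verifies the
two counts agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np

from . import nn

ACTIVATIONS = ("relu", "elu")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the classifier architecture."""

    input_length: int = 187
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernel: int = 3
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    lstm_units: int = 128
    dense_units: int = 512
    dropout: float = 0.5
    n_classes: int = 5
    activation: str = "relu"

    def __post_init__(self):
        sizes = (self.input_length, self.conv_kernel, self.pool_size,
                 self.lstm_units, self.dense_units, self.n_classes,
                 *self.conv_filters)
        if any(int(s) <= 0 for s in sizes):
            raise ValueError("all architecture sizes must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {ACTIVATIONS}, got {self.activation!r}")
        if self.conv_stride != 1 or self.pool_size != self.pool_stride:
            raise ValueError("only stride-1 convolutions and size==stride pooling "
                             "are supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    # -- temporal-length arithmetic under valid padding ------------------
    def conv_lengths(self) -> list[int]:
        """Sequence lengths after each convolution: L, L-2, L-4, L-6 for k=3."""
        lengths = [self.input_length]
        for _ in self.conv_filters:
            lengths.append(lengths[-1] - (self.conv_kernel - 1))
        return lengths[1:]

    def pooled_length(self) -> int:
        return self.conv_lengths()[-1] // self.pool_size

    def validate_lengths(self):
        if self.conv_lengths()[-1] < self.pool_size:
            raise ValueError(
                f"input length {self.input_length} too short for "
                f"{len(self.conv_filters)} valid convolutions and pooling")

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "conv_filters":
                kwargs[key] = tuple(int(x) for x in value.split(","))
            elif key == "activation":
                kwargs[key] = value
            elif key == "dropout":
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class ParameterTable:
    """Per-layer parameter budget of a :class:`ModelSpec`."""

    rows: list[tuple[str, tuple, int]]  # (layer name, output shape, params)
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    @property
    def layer_params(self) -> list[int]:
        return [r[2] for r in self.rows]

    def to_json(self) -> str:
        return json.dumps({
            "rows": [{"layer": n, "output_shape": list(s), "params": p}
                     for n, s, p in self.rows],
            "trainable": self.trainable,
            "non_trainable": self.non_trainable,
            "total": self.total,
        }, indent=2)

    def __str__(self) -> str:
        lines = [f"{'No.':<4}{'Layer':<22}{'Output shape':<16}{'Params':>10}"]
        for i, (name, shape, p) in enumerate(self.rows, start=1):
            lines.append(f"{i:<4}{name:<22}{str(shape):<16}{p:>10,}")
        lines.append(f"Total params: {self.total:,}")
        lines.append(f"Trainable params: {self.trainable:,}")
        lines.append(f"Non-trainable params: {self.non_trainable:,}")
        return "\n".join(lines)


def separable_conv_params(kernel: int, c_in: int, c_out: int) -> int:
    """k*c_in depthwise weights + c_in*c_out pointwise weights + c_out biases."""
    return kernel * c_in + c_in * c_out + c_out


def bilstm_params(units: int, d_in: int) -> int:
    """2 directions x 4 gates x (input + recurrent + bias) weights."""
    return 2 * 4 * (units * (units + d_in) + units)


def parameter_table(spec: ModelSpec) -> ParameterTable:
    """Closed-form per-layer parameter counts for ``spec``."""
    spec.validate_lengths()
    rows: list[tuple[str, tuple, int]] = []
    c_in = 1
    for t_out, c_out in zip(spec.conv_lengths(), spec.conv_filters):
        rows.append(("SeparableConv1D", (t_out, c_out),
                     separable_conv_params(spec.conv_kernel, c_in, c_out)))
        c_in = c_out
    t_conv = spec.conv_lengths()[-1]
    rows.append(("BatchNormalization", (t_conv, c_in), 4 * c_in))
    t_pool = spec.pooled_length()
    rows.append(("MaxPooling1D", (t_pool, c_in), 0))
    state = 2 * spec.lstm_units
    rows.append(("Bidirectional LSTM", (state,),
                 bilstm_params(spec.lstm_units, c_in)))
    rows.append(("Flatten", (state,), 0))
    rows.append(("Dropout", (state,), 0))
    rows.append(("Dense", (spec.dense_units,),
                 state * spec.dense_units + spec.dense_units))
    rows.append(("BatchNormalization", (spec.dense_units,), 4 * spec.dense_units))
    rows.append(("Dense", (spec.n_classes,),
                 spec.dense_units * spec.n_classes + spec.n_classes))
    non_trainable = 2 * c_in + 2 * spec.dense_units  # moving mean+var per BN
    total = sum(r[2] for r in rows)
    return ParameterTable(rows=rows, trainable=total - non_trainable,
                          non_trainable=non_trainable)


@dataclass
class NetworkHandle:
    """A built trainable network together with its spec and parameter table."""

    net: nn.Network
    spec: ModelSpec
    table: ParameterTable = field(repr=False)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    @property
    def n_trainable(self) -> int:
        return self.net.n_trainable

    @property
    def n_non_trainable(self) -> int:
        return self.net.n_non_trainable


def build_network(spec: ModelSpec, seed: int | None = None) -> NetworkHandle:
    """Build the trainable network for ``spec``.

    The engine-reported parameter counts are checked against the closed-form
    :func:`parameter_table`; a mismatch is a bug, not a user error.
    """
    spec.validate_lengths()
    rng = np.random.default_rng(seed)
    act = spec.activation
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in spec.conv_filters:
        layers.append(nn.SeparableConv1D(c_in, c_out, kernel=spec.conv_kernel,
                                         activation=act, rng=rng))
        c_in = c_out
    layers.append(nn.BatchNorm(c_in))
    layers.append(nn.MaxPool1D(spec.pool_size, spec.pool_stride))
    layers.append(nn.BiLSTM(c_in, spec.lstm_units, rng=rng))
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout, rng=rng))
    layers.append(nn.Dense(2 * spec.lstm_units, spec.dense_units,
                           activation=act, rng=rng))
    layers.append(nn.BatchNorm(spec.dense_units))
    layers.append(nn.Dense(spec.dense_units, spec.n_classes,
                           activation="softmax", rng=rng))
    net = nn.Network(layers)
    table = parameter_table(spec)
    assert net.n_trainable == table.trainable, "parameter accounting mismatch"
    assert net.n_non_trainable == table.non_trainable
    return NetworkHandle(net=net, spec=spec, table=table)


def predict(handle: NetworkHandle, segments: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Class-probability rows for ``segments`` of shape (n, L) or (n, L, 1)."""
    x = np.asarray(segments, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3 or x.shape[1] != handle.spec.input_length:
        raise ValueError(
            f"segments must have length {handle.spec.input_length}, "
            f"got shape {segments.shape}")
    out = [handle.net.forward(x[i:i + batch_size], training=False)
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0) if out else np.empty((0, handle.spec.n_classes))
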