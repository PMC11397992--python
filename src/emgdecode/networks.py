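"""Architecture configs and pure functional forms of the network operations.

The model is a causal hybrid: a dilated temporal convolutional network (TCN)
mines local structure from the handcrafted feature sequence; its output is
spliced (concatenated per time step) with those same features and fed to a
deep LSTM stack whose hidden states a linear head maps to one angle per
step.  Every operation is causal — the prediction at window ``t`` depends
only on windows ``0..t``.

The functions here take explicit weight arrays and a single unbatched
sequence, which makes them convenient oracle targets; training uses the
stateful layers in :mod:`emgdecode.nn`, and :mod:`emgdecode.estimators`
wires both together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from . import nn

__all__ = [
    "TCNConfig",
    "LSTMConfig",
    "HybridModelConfig",
    "causal_dilated_conv",
    "residual_block",
    "tcn_forward",
    "lstm_cell",
    "hybrid_forward",
    "build_tcn",
    "build_hybrid",
    "count_parameters",
]


@dataclass(frozen=True)
class TCNConfig:
    """TCN hyperparameters: one residual block per dilation."""

    kernel_size: int = 15
    channels: int = 25
    dilations: tuple[int, ...] = (1, 2, 4)
    dropout_rate: float = 0.0
    convs_per_block: int = 2

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.channels < 1 or self.convs_per_block < 1:
            raise ValueError("kernel_size, channels and convs_per_block must be >= 1")
        object.__setattr__(self, "dilations", tuple(int(d) for d in self.dilations))
        if not self.dilations or any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be a nonempty list of positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def receptive_field(self) -> int:
        """Number of past steps that can influence one output step.

        ``1 + convs_per_block * (K - 1) * sum(dilations)`` — 197 for the
        defaults (K=15, two convs per block, dilations 1+2+4).
        """
        return 1 + self.convs_per_block * (self.kernel_size - 1) * sum(self.dilations)


@dataclass(frozen=True)
class LSTMConfig:
    layers: int = 5
    hidden_units: int = 50

    def __post_init__(self) -> None:
        if self.layers < 1 or self.hidden_units < 1:
            raise ValueError("layers and hidden_units must be >= 1")


@dataclass(frozen=True)
class HybridModelConfig:
    """Full hybrid architecture: TCN -> splice with input -> LSTM -> head."""

    tcn: TCNConfig = field(default_factory=TCNConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    sequence_length: int = 128

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")

    def warn_if_short(self) -> None:
        rf = self.tcn.receptive_field
        if self.sequence_length < rf:
            warnings.warn(
                f"training sequence_length {self.sequence_length} is shorter than "
                f"the TCN receptive field {rf}; early steps of each subsequence "
                "see truncated history",
                stacklevel=2,
            )


def causal_dilated_conv(x: np.ndarray, filt: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Causal dilated convolution of a sequence with one filter.

    ``y[t] = sum_{k=1..K} f_k * x[t - (K - k) * d]`` with zeros for negative
    indices, so the output has the input's length and ``y[t]`` never reads
    past ``x[t]``.  Accepts 1-D ``x`` with a 1-D filter, or ``(T, Cin)`` with
    a ``(K, Cin, Cout)`` filter bank.
    """
    x = np.asarray(x, dtype=float)
    filt = np.asarray(filt, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        if filt.ndim != 1:
            raise ValueError("1-D input requires a 1-D filter")
        x = x[:, None]
        filt = filt[:, None, None]
    if filt.ndim != 3 or filt.shape[1] != x.shape[1]:
        raise ValueError(
            f"filter shape {filt.shape} incompatible with input shape {x.shape}"
        )
    conv = nn.CausalConv1d(x.shape[1], filt.shape[2], filt.shape[0], dilation)
    conv.weight.value = filt
    conv.bias.value = np.zeros(filt.shape[2])
    y = conv.forward(x[None])[0]
    return y[:, 0] if squeeze else y


def residual_block(
    x: np.ndarray,
    config: TCNConfig,
    dilation: int,
    out_channels: int | None = None,
    rng: np.random.Generator | None = None,
    block: nn.TemporalBlock | None = None,
) -> np.ndarray:
    """Run one TCN residual block on an unbatched sequence ``(T, Cin)``.

    Pass ``block`` to reuse fixed weights; otherwise weights are drawn from
    ``rng`` (seeded default).
    """
    x = np.asarray(x, dtype=float)
    if block is None:
        block = nn.TemporalBlock(
            x.shape[1],
            out_channels or config.channels,
            config.kernel_size,
            dilation,
            dropout=config.dropout_rate,
            convs_per_block=config.convs_per_block,
            rng=rng,
        )
    return block.forward(x[None])[0]


def build_tcn(input_dim: int, config: TCNConfig,
              rng: np.random.Generator | None = None) -> nn.Sequential:
    """Stack one residual block per dilation, in the configured order."""
    rng = rng or np.random.default_rng(0)
    blocks: list[nn.Layer] = []
    cin = input_dim
    for d in config.dilations:
        blocks.append(
            nn.TemporalBlock(
                cin, config.channels, config.kernel_size, d,
                dropout=config.dropout_rate,
                convs_per_block=config.convs_per_block, rng=rng,
            )
        )
        cin = config.channels
    return nn.Sequential(blocks)


def tcn_forward(x: np.ndarray, config: TCNConfig,
                rng: np.random.Generator | None = None,
                model: nn.Sequential | None = None) -> np.ndarray:
    """Full TCN on an unbatched ``(T, input_dim)`` sequence -> ``(T, channels)``."""
    x = np.asarray(x, dtype=float)
    if model is None:
        model = build_tcn(x.shape[1], config, rng=rng)
    return model.forward(x[None])[0]


def lstm_cell(x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update with per-gate weights acting on ``[h_prev, x]``.

    ``params`` holds ``W_i, W_f, W_g, W_o`` of shape ``(H, H + I)`` and
    ``b_i, b_f, b_g, b_o`` of shape ``(H,)``:

        i = sigmoid(W_i [h, x] + b_i)     f = sigmoid(W_f [h, x] + b_f)
        g = tanh(W_g [h, x] + b_g)        o = sigmoid(W_o [h, x] + b_o)
        c = f * c_prev + i * g            h = o * tanh(c)
    """
    x = np.asarray(x, dtype=float).ravel()
    h_prev = np.asarray(h_prev, dtype=float).ravel()
    c_prev = np.asarray(c_prev, dtype=float).ravel()
    z = np.concatenate([h_prev, x])
    hs = len(h_prev)
    for gate in ("i", "f", "g", "o"):
        w = np.asarray(params[f"W_{gate}"], dtype=float)
        if w.shape != (hs, len(z)):
            raise ValueError(
                f"W_{gate} has shape {w.shape}, expected ({hs}, {len(z)})"
            )
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    i = sig(params["W_i"] @ z + params["b_i"])
    f = sig(params["W_f"] @ z + params["b_f"])
    g = np.tanh(params["W_g"] @ z + params["b_g"])
    o = sig(params["W_o"] @ z + params["b_o"])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def build_hybrid(input_dim: int, config: HybridModelConfig,
                 rng: np.random.Generator | None = None) -> "HybridNet":
    return HybridNet(input_dim, config, rng=rng)


class HybridNet(nn.Layer):
    """TCN -> per-step splice with the input features -> LSTM stack -> head."""

    def __init__(self, input_dim: int, config: HybridModelConfig,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.config = config
        self.tcn = build_tcn(input_dim, config.tcn, rng=rng)
        fused = config.tcn.channels + input_dim
        layers: list[nn.Layer] = []
        cin = fused
        for _ in range(config.lstm.layers):
            layers.append(nn.LSTMLayer(cin, config.lstm.hidden_units, rng=rng))
            cin = config.lstm.hidden_units
        self.lstm = nn.Sequential(layers)
        self.head = nn.Linear(config.lstm.hidden_units, 1, rng=rng)

    @property
    def fused_dim(self) -> int:
        return self.config.tcn.channels + self.input_dim

    def params(self) -> list[nn.Param]:
        return self.tcn.params() + self.lstm.params() + self.head.params()

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        z = self.tcn.forward(x, train=train)
        fused = np.concatenate([z, x], axis=2)
        h = self.lstm.forward(fused, train=train)
        return self.head.forward(h, train=train)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dy[..., None])
        dfused = self.lstm.backward(dh)
        dz = dfused[:, :, : self.config.tcn.channels]
        dx_skip = dfused[:, :, self.config.tcn.channels :]
        return self.tcn.backward(dz) + dx_skip


def hybrid_forward(features: np.ndarray, config: HybridModelConfig,
                   rng: np.random.Generator | None = None,
                   model: HybridNet | None = None) -> np.ndarray:
    """Hybrid model on an unbatched ``(T, input_dim)`` sequence -> ``(T,)``."""
    features = np.asarray(features, dtype=float)
    if model is None:
        model = build_hybrid(features.shape[1], config, rng=rng)
    return model.forward(features[None])[0]


def count_parameters(model: nn.Layer) -> int:
    return int(sum(p.value.size for p in model.params()))
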