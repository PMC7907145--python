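"""The hybrid network: shared-weight per-frame CNN -> LSTM -> FC -> softmax."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np

from eegtopo.classify.configs import CONFIGS, CnnConfig, flatten_size, layer_sizes
from eegtopo.classify.layers import (
    DTYPE,
    Conv2D,
    Dense,
    Dropout,
    Layer,
    LSTM,
    MaxPool2,
    Param,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = ["LstmSpec", "HybridNet", "build_model", "count_parameters"]


@dataclass(frozen=True)
class LstmSpec:
    hidden_size: int = 128

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


class HybridNet:
    """Time-distributed CNN embedding of each frame, LSTM over the frame
    embeddings, dropout, and a final 2-unit softmax head.

    Input: (batch, n_frames, size, size, 3) float arrays in [0, 1].
    The CNN weights are shared across frames.
    """

    def __init__(
        self,
        cnn: CnnConfig,
        lstm: LstmSpec = LstmSpec(),
        n_frames: int = 6,
        image_size: int = 32,
        in_channels: int = 3,
        n_classes: int = 2,
        dropout: float = 0.5,
        seed: int = 0,
    ) -> None:
        layer_sizes(cnn, image_size, in_channels)  # raises on inconsistent shapes
        self.cnn_config = cnn
        self.lstm_spec = lstm
        self.n_frames = n_frames
        self.image_size = image_size
        self.in_channels = in_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**63))

        self.cnn_layers: List[Layer] = []
        c_prev = in_channels
        first = True
        for count, kernels in cnn.conv_plan:
            for _ in range(count):
                self.cnn_layers.append(Conv2D(c_prev, kernels, rng, input_grad=not first))
                first = False
                self.cnn_layers.append(ReLU())
                c_prev = kernels
            self.cnn_layers.append(MaxPool2())
        flat = flatten_size(cnn, image_size, in_channels)
        self.fc_embed = Dense(flat, cnn.fc_nodes, rng)
        self.fc_relu = ReLU()
        self.fc_drop = Dropout(dropout, self._dropout_rng)
        self.lstm = LSTM(cnn.fc_nodes, lstm.hidden_size, rng)
        self.head_drop = Dropout(dropout, self._dropout_rng)
        self.head = Dense(lstm.hidden_size, n_classes, rng)

    # -- plumbing ---------------------------------------------------------

    def parameters(self) -> List[Param]:
        params: List[Param] = []
        for layer in self.cnn_layers:
            params.extend(layer.params())
        for layer in (self.fc_embed, self.lstm, self.head):
            params.extend(layer.params())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_state(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.fc_drop.rng = rng
        self.head_drop.rng = rng

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 5 or x.shape[3] != x.shape[2] or x.shape[4] != self.in_channels:
            raise ValueError(
                f"expected (batch, frames, {self.image_size}, {self.image_size}, "
                f"{self.in_channels}), got {x.shape}"
            )
        batch, frames = x.shape[0], x.shape[1]
        # fold frames into the batch axis; channels outermost for the CNN
        h = np.ascontiguousarray(x.reshape(-1, *x.shape[2:]).transpose(3, 0, 1, 2))
        for layer in self.cnn_layers:
            h = layer.forward(h, train)
        # (C, N, s, s) -> (N, C*s*s) for the embedding layer
        h = np.ascontiguousarray(h.transpose(1, 0, 2, 3)).reshape(h.shape[1], -1)
        h = self.fc_embed.forward(h, train)
        h = self.fc_relu.forward(h, train)
        h = self.fc_drop.forward(h, train)
        h = h.reshape(batch, frames, -1)
        h = self.lstm.forward(h, train)
        h = self.head_drop.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.head_drop.backward(d)
        d = self.lstm.backward(d)
        d = d.reshape(-1, d.shape[-1])
        d = self.fc_drop.backward(d)
        d = self.fc_relu.backward(d)
        d = self.fc_embed.backward(d)
        # unflatten to the last CNN feature-map shape, channels outermost
        trace = layer_sizes(self.cnn_config, self.image_size, self.in_channels)
        size, channels = trace[-3][1], trace[-3][2]
        d = np.ascontiguousarray(d.reshape(-1, channels, size, size).transpose(1, 0, 2, 3))
        for layer in reversed(self.cnn_layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.vstack(out)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy on a batch; accumulates parameter gradients."""
        logits = self.forward(x, train=True)
        loss, probs, dlogits = softmax_cross_entropy(logits, y)
        self.backward(dlogits)
        return loss, probs


def build_model(
    cnn: Union[str, CnnConfig],
    lstm: LstmSpec = LstmSpec(),
    n_frames: int = 6,
    image_size: int = 32,
    in_channels: int = 3,
    n_classes: int = 2,
    dropout: float = 0.5,
    seed: int = 0,
) -> HybridNet:
    if isinstance(cnn, str):
        if cnn not in CONFIGS:
            raise ValueError(f"unknown CNN configuration {cnn!r}; choose from {sorted(CONFIGS)}")
        cnn = CONFIGS[cnn]
    return HybridNet(
        cnn,
        lstm,
        n_frames=n_frames,
        image_size=image_size,
        in_channels=in_channels,
        n_classes=n_classes,
        dropout=dropout,
        seed=seed,
    )


def count_parameters(model: HybridNet) -> int:
    return int(sum(p.size for p in model.parameters()))
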