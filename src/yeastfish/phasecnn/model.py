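"""Network architecture and (de)serialization.

Five convolutional blocks (conv -> batch norm -> channel attention ->
spatial attention -> ReLU -> 2x2 max pool), filter counts doubling from 32
to 512, followed by one fully connected block with dropout and a 9-way
output layer.  An 80 px input shrinks 80 -> 40 -> 20 -> 10 -> 5 -> 2.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from yeastfish.exceptions import ConfigurationError
from yeastfish.phasecnn import layers as L
from yeastfish.phases import PHASES


@dataclass(frozen=True)
class CnnConfig:
    n_blocks: int = 5
    base_filters: int = 32
    kernel_size: int = 3
    fc_hidden: int = 256
    dropout_rate: float = 0.5
    n_classes: int = 9
    attention: bool = True
    input_size: int = 80
    learning_rate: float = 1e-3
    focal_alpha: float = 1.0
    focal_gamma: float = 2.0
    batch_size: int = 64
    epochs: int = 10
    augment: bool = True
    seed: int = 0

    @property
    def filters(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**i for i in range(self.n_blocks))

    @property
    def final_spatial(self) -> int:
        s = self.input_size
        for _ in range(self.n_blocks):
            s //= 2
        if s < 1:
            raise ConfigurationError("input too small for the number of blocks")
        return s


CLASSES = PHASES  # index <-> label mapping for predictions


def build_model(cfg: CnnConfig, n_channels: int = 3) -> L.Sequential:
    """Fresh network with He-initialised weights (seeded by cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    stack: list[L.Layer] = [L.ToChannelMajor()]
    cin = n_channels
    for cout in cfg.filters:
        stack.append(L.Conv2d(cin, cout, cfg.kernel_size, rng))
        stack.append(L.BatchNorm2d(cout))
        if cfg.attention:
            stack.append(L.ChannelAttention(cout, rng))
            stack.append(L.SpatialAttention(rng))
        stack.append(L.ReLU())
        stack.append(L.MaxPool2())
        cin = cout
    stack.append(L.Flatten())
    flat = cfg.filters[-1] * cfg.final_spatial**2
    stack.append(L.Linear(flat, cfg.fc_hidden, rng))
    stack.append(L.ReLU())
    stack.append(L.Dropout(cfg.dropout_rate, rng))
    stack.append(L.Linear(cfg.fc_hidden, cfg.n_classes, rng))
    model = L.Sequential(stack)
    model.config = cfg
    return model


def save_model(model: L.Sequential, path) -> None:
    state = {
        "config": model.config,
        "params": [p.value for p in model.params()],
        "bn": [
            (l.running_mean, l.running_var)
            for l in model.layers
            if isinstance(l, L.BatchNorm2d)
        ],
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_model(path) -> L.Sequential:
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    model = build_model(state["config"])
    for p, value in zip(model.params(), state["params"]):
        p.value[...] = value
    bn_layers = [l for l in model.layers if isinstance(l, L.BatchNorm2d)]
    for l, (mean, var) in zip(bn_layers, state["bn"]):
        l.running_mean[...] = mean
        l.running_var[...] = var
    return model
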