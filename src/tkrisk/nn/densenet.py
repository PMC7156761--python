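"""Densely connected convolutional risk classifier (2D or 3D).

The reference architecture follows DenseNet-121: an initial strided
convolution and pooling stage, four dense blocks of bottlenecked
(1x1 then 3x3) composite layers joined by feature concatenation, halving
transition layers between blocks, and a 2-class linear head over globally
pooled features. Full-scale parameters are 16 initial filters, growth rate
32, block configuration [6, 12, 24, 16] and bottleneck width 4; the desk
preset shrinks every dimension so the network trains on a CPU in minutes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from tkrisk.nn import layers as L

__all__ = ["DenseNetConfig", "DenseNet", "build_model", "predict_risk"]


@dataclass(frozen=True)
class DenseNetConfig:
    dimensionality: int = 3
    initial_filters: int = 16
    growth_rate: int = 32
    block_config: tuple[int, ...] = (6, 12, 24, 16)
    bottleneck_layers: int = 4  # bottleneck width multiplier (1x1 conv width / growth)
    n_classes: int = 2
    dropout_rate: float = 0.0
    negative_slope: float = 0.01
    init_kernel: int = 7
    init_stride: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if not self.block_config or any(b < 1 for b in self.block_config):
            raise ValueError("block_config must be nonempty with entries >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @staticmethod
    def desk_scale(dimensionality: int = 3, dropout_rate: float = 0.0,
                   seed: int = 0) -> "DenseNetConfig":
        """Small configuration for 24 x 48 x 48 (or 48 x 48) inputs."""
        return DenseNetConfig(
            dimensionality=dimensionality,
            initial_filters=8,
            growth_rate=8,
            block_config=(2, 4, 4, 2),
            bottleneck_layers=4,
            dropout_rate=dropout_rate,
            init_kernel=3,
            init_stride=2,
            seed=seed,
        )


class DenseNet:
    """The assembled network; layers are enumerable in depth order."""

    def __init__(self, config: DenseNetConfig):
        self.config = config
        nd = config.dimensionality
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(config.seed + 1)
        g = config.growth_rate
        bn_width = config.bottleneck_layers * g

        def dense_layer(in_ch: int) -> L.Sequential:
            return L.Sequential([
                L.BatchNorm(in_ch),
                L.LeakyReLU(config.negative_slope),
                L.Conv(in_ch, bn_width, 1, nd, rng=rng),
                L.BatchNorm(bn_width),
                L.LeakyReLU(config.negative_slope),
                L.Conv(bn_width, g, 3, nd, padding=1, rng=rng),
                L.Dropout(config.dropout_rate, rng=self.dropout_rng),
            ])

        mods: list[L.Module] = [
            L.Conv(1, config.initial_filters, config.init_kernel, nd,
                   stride=config.init_stride,
                   padding=config.init_kernel // 2, rng=rng),
            L.BatchNorm(config.initial_filters),
            L.LeakyReLU(config.negative_slope),
            L.AvgPool2(),
        ]
        ch = config.initial_filters
        for i, n_layers in enumerate(config.block_config):
            block_layers = []
            for _ in range(n_layers):
                block_layers.append(dense_layer(ch))
                ch += g
            mods.append(L.DenseBlock(block_layers))
            if i < len(config.block_config) - 1:
                out_ch = ch // 2
                mods.append(L.Sequential([
                    L.BatchNorm(ch),
                    L.LeakyReLU(config.negative_slope),
                    L.Conv(ch, out_ch, 1, nd, rng=rng),
                    L.AvgPool2(),
                ]))
                ch = out_ch
        mods += [
            L.BatchNorm(ch),
            L.LeakyReLU(config.negative_slope),
            L.GlobalAvgPool(),
        ]
        self.trunk = L.Sequential(mods)
        self.head = L.Linear(ch, config.n_classes, rng=rng)
        self.n_features = ch

    # -- structure -----------------------------------------------------

    def parameterized_modules(self) -> list[L.Module]:
        """Leaf modules holding parameters, in depth order; head is last."""

        def leaves(module: L.Module):
            if isinstance(module, L.DenseBlock):
                for layer in module.layers:
                    yield from leaves(layer)
            elif isinstance(module, L.Sequential):
                for m in module.modules:
                    yield from leaves(m)
            elif module.params():
                yield module

        return list(leaves(self.trunk)) + [self.head]

    def set_frozen(self, frozen_layers: int) -> None:
        """Freeze the first ``frozen_layers`` parameterized layers.

        The classification head is exempt and always stays trainable; a
        count at or above the number of non-head layers freezes the whole
        trunk ("all but head").
        """
        mods = self.parameterized_modules()
        trunk_mods = mods[:-1]
        for i, m in enumerate(trunk_mods):
            m.trainable = i >= frozen_layers
        self.head.trainable = True

    def unfreeze_all(self) -> None:
        for m in self.parameterized_modules():
            m.trainable = True

    def set_dropout(self, rate: float) -> None:
        def visit(module):
            if isinstance(module, L.Dropout):
                module.rate = rate
            elif isinstance(module, L.DenseBlock):
                for layer in module.layers:
                    visit(layer)
            elif isinstance(module, L.Sequential):
                for m in module.modules:
                    visit(m)

        visit(self.trunk)

    def architecture_signature(self) -> list[tuple[str, tuple[tuple[int, ...], ...]]]:
        return [
            (type(m).__name__, tuple(p.value.shape for p in m.params()))
            for m in self.parameterized_modules()
        ]

    def n_parameters(self) -> int:
        return sum(p.value.size for m in self.parameterized_modules()
                   for p in m.params())

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameters AND batch-norm running statistics.

        Running statistics must travel with the weights: restoring an
        earlier epoch's weights against later running averages puts
        inference-mode normalization out of step with the features.
        """
        arrays: list[np.ndarray] = []
        for m in self.parameterized_modules():
            for p in m.params():
                arrays.append(p.value.copy())
            if isinstance(m, L.BatchNorm):
                arrays.append(m.running_mean.copy())
                arrays.append(m.running_var.copy())
        return arrays

    def load_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for m in self.parameterized_modules():
            for p in m.params():
                p.value[...] = next(it)
            if isinstance(m, L.BatchNorm):
                m.running_mean[...] = next(it)
                m.running_var[...] = next(it)

    # -- computation ---------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        nd = self.config.dimensionality
        x = np.asarray(x, dtype=L.DTYPE)
        if x.ndim == nd:
            x = x[None]
        if x.ndim != nd + 1:
            raise ValueError(
                f"expected input of {nd} spatial axes (optionally batched), "
                f"got array of shape {x.shape}"
            )
        return x[..., None]  # channels-last

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.trunk.forward(self._check_input(x), train=train)
        return self.head.forward(feats, train=train)

    def backward(self, grad_logits: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(grad_logits))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode; shape (n, n_classes)."""
        return L.softmax(self.forward(x, train=False))

    def copy(self) -> "DenseNet":
        return copy.deepcopy(self)


def build_model(config: DenseNetConfig) -> DenseNet:
    """Construct the classifier; architecture is a pure function of config."""
    return DenseNet(config)


def predict_risk(model: DenseNet, volume: np.ndarray) -> float | np.ndarray:
    """Probability of the TKR class (class 1), in [0, 1].

    A single volume returns a scalar; a batched input returns one value per
    volume. Deterministic in inference mode.
    """
    p = model.predict_proba(volume)[:, 1]
    arr = np.asarray(volume)
    if arr.ndim == model.config.dimensionality:
        return float(p[0])
    return p
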