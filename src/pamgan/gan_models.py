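"""Residual generator and Markovian patch discriminator.

The generator is the classic residual translation network: a 7x7 stem,
strided-convolution encoder, a stack of residual blocks (nine at full
scale) and a mirrored decoder, ending in a tanh rescaled to [0, 1] to
match 8-bit-normalized amplitude patches.  The discriminator is a patch
discriminator (stacked strided 4x4 convolutions) whose sigmoid decisions
form a spatial map; a ``global_scalar`` mode mean-pools the map to a
single 1x1 decision.  Both are pure tensor-to-tensor functions of their
(seeded) parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Topology of the translation generator (full-scale defaults)."""

    n_res_blocks: int = 9
    base_filters: int = 64
    n_downsamples: int = 2
    in_channels: int = 1
    out_channels: int = 1
    norm: str = "instance"     # {"instance", "batch"}
    padding: str = "reflect"   # {"reflect", "zero"}

    def __post_init__(self) -> None:
        if self.n_res_blocks < 1:
            raise SpecError("n_res_blocks must be >= 1")
        if self.base_filters < 4:
            raise SpecError("base_filters must be >= 4")
        if self.n_downsamples < 0:
            raise SpecError("n_downsamples must be >= 0")
        if self.norm not in ("instance", "batch"):
            raise SpecError(f"unknown norm {self.norm!r}")
        if self.padding not in ("reflect", "zero"):
            raise SpecError(f"unknown padding {self.padding!r}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Topology of the patch discriminator.

    ``in_channels=2`` for the conditioned case (source and candidate
    concatenated on the channel axis); 1 for unconditioned discriminators.
    """

    base_filters: int = 64
    n_layers: int = 3
    decision_mode: str = "patch_map"  # {"patch_map", "global_scalar"}
    in_channels: int = 2
    norm: str = "instance"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise SpecError("n_layers must be >= 1")
        if self.decision_mode not in ("patch_map", "global_scalar"):
            raise SpecError(f"unknown decision_mode {self.decision_mode!r}")


class Generator:
    """Callable image-to-image network; output shape equals input shape."""

    def __init__(self, spec: GeneratorSpec, net: nn.Sequential, seed: int) -> None:
        self.spec = spec
        self.net = net
        self.seed = seed

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        div = 2 ** self.spec.n_downsamples
        if x.shape[2] % div or x.shape[3] % div:
            raise SpecError(
                f"input {x.shape[2:]} not divisible by 2^{self.spec.n_downsamples}"
            )
        return x

    def forward(self, x: np.ndarray):
        return self.net.forward(self._check(x))

    def backward(self, tape, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(tape, dy)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        squeeze = np.asarray(x).ndim == 2
        y, _ = self.forward(x)
        return y[0, 0] if squeeze else y


class Discriminator:
    """Callable patch discriminator; decisions lie in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, net: nn.Sequential, seed: int) -> None:
        self.spec = spec
        self.net = net
        self.seed = seed

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise SpecError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        return self.net.forward(x)

    def backward(self, tape, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(tape, dy)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x)
        return y


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Assemble stem -> encoder -> residual blocks -> decoder -> bounded output."""
    rng = np.random.default_rng([int(seed), 0x6E])
    pad_mode = "reflect" if spec.padding == "reflect" else "zero"
    layers: list[nn.Layer] = [
        nn.Conv2d(spec.in_channels, spec.base_filters, 7, pad_mode=pad_mode, rng=rng),
        nn._make_norm(spec.norm, spec.base_filters),
        nn.ReLU(),
    ]
    ch = spec.base_filters
    for _ in range(spec.n_downsamples):
        layers += [
            nn.Conv2d(ch, ch * 2, 3, stride=2, pad=1, pad_mode="zero", rng=rng),
            nn._make_norm(spec.norm, ch * 2),
            nn.ReLU(),
        ]
        ch *= 2
    for _ in range(spec.n_res_blocks):
        layers.append(nn.ResidualBlock(ch, rng, pad_mode=pad_mode, norm=spec.norm))
    for _ in range(spec.n_downsamples):
        layers += [
            nn.UpsampleNearest2(),
            nn.Conv2d(ch, ch // 2, 3, pad_mode="zero", rng=rng),
            nn._make_norm(spec.norm, ch // 2),
            nn.ReLU(),
        ]
        ch //= 2
    layers += [
        nn.Conv2d(ch, spec.out_channels, 7, pad_mode=pad_mode, rng=rng),
        nn.TanhUnit(),
    ]
    return Generator(spec, nn.Sequential(layers), seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    """Stacked strided 4x4 convolutions ending in sigmoid patch decisions."""
    rng = np.random.default_rng([int(seed), 0xD1])
    layers: list[nn.Layer] = [
        nn.Conv2d(spec.in_channels, spec.base_filters, 4, stride=2, pad=1,
                  pad_mode="zero", rng=rng),
        nn.LeakyReLU(0.2),
    ]
    ch = spec.base_filters
    for i in range(1, spec.n_layers):
        ch_out = spec.base_filters * min(2**i, 8)
        layers += [
            nn.Conv2d(ch, ch_out, 4, stride=2, pad=1, pad_mode="zero", rng=rng),
            nn._make_norm(spec.norm, ch_out),
            nn.LeakyReLU(0.2),
        ]
        ch = ch_out
    ch_out = spec.base_filters * min(2**spec.n_layers, 8)
    layers += [
        nn.Conv2d(ch, ch_out, 4, stride=1, pad=1, pad_mode="zero", rng=rng),
        nn._make_norm(spec.norm, ch_out),
        nn.LeakyReLU(0.2),
        nn.Conv2d(ch_out, 1, 4, stride=1, pad=1, pad_mode="zero", rng=rng),
        nn.Sigmoid(),
    ]
    if spec.decision_mode == "global_scalar":
        layers.append(nn.GlobalMeanPool())
    return Discriminator(spec, nn.Sequential(layers), seed)


def count_parameters(net: Generator | Discriminator) -> int:
    return nn.count_parameters(net.net)
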