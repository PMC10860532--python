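"""Generator and discriminator architectures.

The generator is a U-Net-shaped encoder-decoder with residual blocks in
place of plain convolutions and skip connections between mirrored levels.
Each encoder level halves every spatial axis (stride-2 first convolution of
its residual block); each decoder level restores it by trilinear 2x
interpolation followed by convolution — interpolation-then-convolution
avoids the checkerboard artifacts of transposed convolutions.  The head
predicts a tanh-bounded correction added to the input (global residual),
clipped to the normalized intensity range [-1, 1]: contrast removal is a
sparse perturbation of an identity map, so the identity is made free.

The discriminator is a conditional patch-score CNN (PatchGAN): the source
CECT patch and the real/generated NCECT candidate are concatenated on the
channel axis, passed through stride-2 convolutions, and projected to a grid
of per-patch probabilities that is flattened to a 1D score vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, Module, Conv3d, InstanceNorm3d
from .nn.autograd import concat


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Scale knobs for the residual U-Net generator.

    ``patch_size`` must be divisible by ``2**n_levels`` on every axis.  With
    the full-scale defaults (4 levels, base 64 doubling to a 512 cap) a
    256x256x64 patch is encoded to a 16x16x4 bottleneck with 512 channels
    and decoded back to 256x256x64.
    """

    n_levels: int = 4
    base_channels: int = 64
    max_channels: int = 512
    n_bottleneck_residual_blocks: int = 1
    patch_size: tuple = (256, 256, 64)

    def __post_init__(self):
        if self.n_levels < 1 or self.base_channels < 1:
            raise ConfigError("n_levels and base_channels must be positive")
        d = 2**self.n_levels
        bad = [p for p in self.patch_size if p % d != 0 or p < d]
        if bad:
            raise ConfigError(
                f"patch_size {self.patch_size} not divisible by 2**n_levels = {d}"
            )

    @property
    def level_channels(self):
        return [
            min(self.base_channels * 2**i, self.max_channels)
            for i in range(self.n_levels)
        ]

    def bottleneck_shape(self):
        d = 2**self.n_levels
        return (self.level_channels[-1],) + tuple(p // d for p in self.patch_size)


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Patch-score discriminator: ``n_layers`` stride-2 convolutions."""

    n_layers: int = 3
    base_channels: int = 64
    max_channels: int = 256
    kernel_size: int = 4
    conditional: bool = True
    patch_size: tuple = (256, 256, 64)

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        d = 2**self.n_layers
        bad = [p for p in self.patch_size if p < d or p % d != 0]
        if bad:
            raise ConfigError(
                f"patch_size {self.patch_size} too small for {self.n_layers} "
                f"stride-2 halvings (needs multiples of {d})"
            )

    def score_grid_shape(self):
        d = 2**self.n_layers
        return tuple(p // d for p in self.patch_size)


class ResidualBlock(Module):
    """conv-norm-ReLU-conv-norm plus identity shortcut; ReLU after addition.

    A stride of 2 in the first convolution makes the block the downsampling
    unit of an encoder level; the shortcut then uses a 1x1x1 projection.
    """

    def __init__(self, in_channels, out_channels, stride=1, rng=None):
        self.conv1 = Conv3d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.norm1 = InstanceNorm3d(out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng=rng)
        self.norm2 = InstanceNorm3d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv3d(in_channels, out_channels, 1, stride=stride,
                               padding=(0, 0, 0), rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        shortcut = x if self.proj is None else self.proj(x)
        return nn.relu(h + shortcut)


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        ch = cfg.level_channels
        self.encoders = []
        c_in = 1
        for c in ch:
            self.encoders.append(ResidualBlock(c_in, c, stride=2, rng=rng))
            c_in = c
        self.bottleneck = [
            ResidualBlock(ch[-1], ch[-1], rng=rng)
            for _ in range(cfg.n_bottleneck_residual_blocks)
        ]
        self.up_convs = []
        self.dec_blocks = []
        for i in range(cfg.n_levels - 1, 0, -1):
            self.up_convs.append(Conv3d(ch[i], ch[i - 1], 3, rng=rng))
            self.dec_blocks.append(ResidualBlock(2 * ch[i - 1], ch[i - 1], rng=rng))
        self.final_up = Conv3d(ch[0], ch[0], 3, rng=rng)
        # full-resolution skip is the input patch itself (1 channel); a
        # residual block after the concat lets the head form voxelwise
        # interactions between structure features and raw intensity
        self.refine = ResidualBlock(ch[0] + 1, ch[0], rng=rng)
        self.head = Conv3d(ch[0], 1, 3, rng=rng)

    def forward(self, x: Tensor, return_features: bool = False):
        if x.shape[0] != 1:
            raise ValueError(f"generator expects a 1-channel patch, got {x.shape}")
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
        for blk in self.bottleneck:
            h = blk(h)
        bottleneck = h
        for up, blk, skip in zip(self.up_convs, self.dec_blocks, skips[-2::-1]):
            h = up(nn.upsample2x(h))
            h = blk(concat([h, skip], axis=0))
        h = self.final_up(nn.upsample2x(h))
        # global-residual head: the network predicts the bounded contrast
        # correction to add to the input; the identity map costs nothing to
        # represent, so capacity goes into modelling the enhancement field.
        correction = nn.tanh(self.head(self.refine(concat([h, x], axis=0))))
        out = (x + correction).clip(-1.0, 1.0)
        if return_features:
            return out, {"bottleneck": bottleneck}
        return out


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        c_in = 2 if cfg.conditional else 1
        self.convs = []
        self.norms = []
        for i in range(cfg.n_layers):
            c_out = min(cfg.base_channels * 2**i, cfg.max_channels)
            self.convs.append(
                Conv3d(c_in, c_out, cfg.kernel_size, stride=2, padding=(1, 1, 1),
                       rng=rng)
            )
            # pix2pix convention: no normalization on the first layer
            self.norms.append(InstanceNorm3d(c_out) if i > 0 else None)
            c_in = c_out
        self.head = Conv3d(c_in, 1, 3, rng=rng)

    def forward(self, condition: Tensor, candidate: Tensor) -> Tensor:
        """Score (condition, candidate); returns a flat vector in (0, 1)."""
        if self.cfg.conditional:
            h = concat([condition, candidate], axis=0)
        else:
            h = candidate
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = nn.leaky_relu(h, 0.2)
        return nn.sigmoid(self.head(h)).flatten()


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    """Instantiate the residual U-Net generator with seeded weights."""
    return Generator(cfg, seed=seed)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    """Instantiate the conditional patch-score discriminator."""
    return Discriminator(cfg, seed=seed)
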