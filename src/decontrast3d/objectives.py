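"""Training objectives: adversarial, L1, perceptual, and their combination.

The adversarial objective is the classic log-loss (vanilla GAN) form: the
discriminator maximizes E[log D(x, y)] + E[log(1 - D(x, G(x)))]; the
generator uses the standard non-saturating variant -E[log D(x, G(x))].
Reconstruction is a voxelwise L1 term, and a perceptual term compares
feature maps of a fixed extractor, each layer normalized by its element
count:  sum_i (1/M_i) * sum |F_i(y) - F_i(G(x))|.  The total generator
objective is  L_adv + lambda * L_1 + delta * L_perc  with both weights
defaulting to 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Conv3d
from . import nn

logger = logging.getLogger(__name__)

SCORE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights of the L1 (lambda) and perceptual (delta) terms."""

    lambda_l1: float = 10.0
    delta_perc: float = 10.0

    def __post_init__(self):
        if not (np.isfinite(self.lambda_l1) and np.isfinite(self.delta_perc)):
            raise ValueError("loss weights must be finite")
        if self.lambda_l1 < 0 or self.delta_perc < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _clamped(scores: Tensor) -> Tensor:
    lo, hi = SCORE_EPS, 1.0 - SCORE_EPS
    if scores.data.min() < lo or scores.data.max() > hi:
        logger.debug("discriminator scores clamped to [%g, %g]", lo, hi)
    return scores.clip(lo, hi)


def adversarial_loss_discriminator(real_scores, fake_scores) -> Tensor:
    """Mean BCE pushing real scores to 1 and fake scores to 0 (minimized)."""
    r = _clamped(_as_tensor(real_scores))
    f = _clamped(_as_tensor(fake_scores))
    return -(r.log().mean()) - ((1.0 - f).log().mean())


def adversarial_loss_generator(fake_scores) -> Tensor:
    """Non-saturating generator loss -mean log D(G(x))."""
    f = _clamped(_as_tensor(fake_scores))
    return -(f.log().mean())


def l1_loss(generated, target) -> Tensor:
    """Mean absolute voxel difference."""
    g, t = _as_tensor(generated), _as_tensor(target)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    return (g - t).abs().mean()


class FeatureExtractor(Module):
    """Fixed (non-trained) seeded random 3-layer 3D convolution stack.

    Random convolutional features are a deterministic, download-free basis
    for a perceptual distance on 3D patches; the extractor contract (an
    ordered list of feature maps) also admits pretrained slice-wise
    extractors as plug-ins.
    """

    def __init__(self, channels=(8, 8, 8), kernel_size=3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c_in = 1
        for c in channels:
            # He-style scale keeps activations O(1) through the stack
            std = float(np.sqrt(2.0 / (c_in * kernel_size**3)))
            self.convs.append(
                Conv3d(c_in, c, kernel_size, stride=2, rng=rng, init_std=std)
            )
            c_in = c
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor):
        """Return the ordered list of feature maps for a (1, X, Y, Z) patch."""
        feats = []
        h = x
        for conv in self.convs:
            h = nn.relu(conv(h))
            feats.append(h)
        return feats


class IdentityExtractor(Module):
    """Single layer F1(x) = x; collapses the perceptual loss to plain L1."""

    def forward(self, x: Tensor):
        return [x]


def perceptual_loss(generated, target, fx: Module) -> Tensor:
    """sum_i (1/M_i) * sum |F_i(target) - F_i(generated)|."""
    g, t = _as_tensor(generated), _as_tensor(target)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    feats_g = fx(g)
    feats_t = fx(t.detach())
    total = None
    for fg, ft in zip(feats_g, feats_t):
        term = (ft.detach() - fg).abs().sum() / float(fg.size)
        total = term if total is None else total + term
    return total


def total_generator_loss(adv, l1, perc, w: LossWeights = LossWeights()):
    """adv + lambda * l1 + delta * perceptual."""
    return adv + w.lambda_l1 * l1 + w.delta_perc * perc
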