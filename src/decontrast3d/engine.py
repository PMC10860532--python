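"""Training loop and whole-volume inference by overlapping-patch stitching.

Training alternates one discriminator update (real pair vs detached fake)
and one generator update (adversarial + weighted L1 + weighted perceptual)
per patch, mini-batch size 1, Adam for both networks.  The learning rate is
constant for the first half of the schedule and decays linearly to zero
over the second half.

Inference tiles a whole volume with overlapping patches on a regular grid,
runs each patch through the generator in normalized intensity space, and
averages the predictions voxelwise over all covering patches (uniform
"simple averaging"), then maps back to HU.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .volume import Volume
from .preprocess import (
    NormalizationSpec,
    normalize_array,
    denormalize_array,
    sample_patches,
)
from .networks import (
    GeneratorConfig,
    DiscriminatorConfig,
    Generator,
    Discriminator,
    build_generator,
    build_discriminator,
)
from .objectives import (
    LossWeights,
    FeatureExtractor,
    adversarial_loss_discriminator,
    adversarial_loss_generator,
    l1_loss,
    perceptual_loss,
    total_generator_loss,
)
from .nn import Tensor, Adam, Module, no_grad
from .nn.autograd import default_dtype

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    total_epochs: int = 200
    const_lr_epochs: int = 100
    initial_lr: float = 2e-4
    betas: tuple = (0.5, 0.999)
    batch_size: int = 1
    patches_per_case: int = 4
    seed: int = 0
    checkpoint_every: int = 0  # 0 = final checkpoint only
    extractor_seed: int = 0
    dtype: str = "float32"  # training compute dtype; float64 for exactness studies

    def __post_init__(self):
        if self.const_lr_epochs > self.total_epochs:
            raise ValueError(
                f"const_lr_epochs {self.const_lr_epochs} exceeds "
                f"total_epochs {self.total_epochs}"
            )
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.batch_size != 1:
            raise ValueError("only mini-batch size 1 is supported")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Constant then linear-to-zero learning-rate schedule (1-based epochs)."""
    if not (1 <= epoch <= cfg.total_epochs):
        raise ValueError(f"epoch {epoch} outside [1, {cfg.total_epochs}]")
    if epoch <= cfg.const_lr_epochs:
        return cfg.initial_lr
    decay_span = cfg.total_epochs - cfg.const_lr_epochs
    return cfg.initial_lr * (cfg.total_epochs - epoch) / decay_span


@dataclass
class StitchPlan:
    patch_size: tuple
    stride: tuple
    corners: list
    volume_shape: tuple

    def coverage(self) -> np.ndarray:
        cov = np.zeros(self.volume_shape, dtype=np.int32)
        for c in self.corners:
            sl = tuple(slice(a, a + s) for a, s in zip(c, self.patch_size))
            cov[sl] += 1
        return cov


def plan_patches(volume_shape, patch_size, overlap_fraction: float = 0.5) -> StitchPlan:
    """Regular overlapping tiling with the final patch clamped to the border.

    ``stride = patch * (1 - overlap)``; every voxel is covered at least once.
    """
    if not (0.0 <= overlap_fraction <= 0.9):
        raise ValueError(f"overlap_fraction {overlap_fraction} outside [0, 0.9]")
    volume_shape = tuple(int(s) for s in volume_shape)
    patch_size = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(patch_size, volume_shape)):
        raise ValueError(f"patch {patch_size} exceeds volume {volume_shape}")
    stride = tuple(max(1, int(round(p * (1.0 - overlap_fraction)))) for p in patch_size)
    axes = []
    for n, p, st in zip(volume_shape, patch_size, stride):
        pos = list(range(0, n - p + 1, st))
        if pos[-1] != n - p:
            pos.append(n - p)
        axes.append(pos)
    corners = [
        (i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]
    ]
    return StitchPlan(patch_size, stride, corners, volume_shape)


def _patch_fn(generator):
    """Adapt a Generator module or a plain array callable to ndarray->ndarray."""
    if isinstance(generator, Module):
        def fn(arr):
            with no_grad():
                return generator(Tensor(arr[None])).data[0]
        return fn
    return generator


def convert_volume(generator, cect: Volume, plan: StitchPlan,
                   norm: NormalizationSpec = NormalizationSpec()) -> Volume:
    """Run patchwise inference over a whole volume and stitch by averaging.

    Volumes smaller than the patch on any axis are reflect-padded up to the
    patch size and cropped back after inference.
    """
    grid = np.asarray(cect.grid, dtype=np.float64)
    pad = [max(0, p - s) for p, s in zip(plan.patch_size, grid.shape)]
    if any(pad):
        grid = np.pad(grid, [(0, p) for p in pad], mode="reflect")
        plan = plan_patches(grid.shape, plan.patch_size)
    if tuple(plan.volume_shape) != grid.shape:
        raise ValueError(
            f"stitch plan for shape {plan.volume_shape} does not match "
            f"volume shape {grid.shape}"
        )
    fn = _patch_fn(generator)
    normed = normalize_array(grid, norm)
    acc = np.zeros_like(normed)
    count = np.zeros(grid.shape, dtype=np.int32)
    for idx, corner in enumerate(plan.corners):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, plan.patch_size))
        pred = fn(normed[sl])
        if pred.shape != tuple(plan.patch_size):
            raise ValueError(
                f"generator returned shape {pred.shape}, expected {plan.patch_size}"
            )
        acc[sl] += pred
        count[sl] += 1
    assert count.min() >= 1, "stitch plan left voxels uncovered"
    out = denormalize_array(acc / count, norm)
    if any(pad):
        out = out[tuple(slice(0, s) for s in cect.shape)]
    return Volume(out, cect.spacing_mm, cect.origin_mm)


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    history: list  # per-epoch dicts of mean losses
    config: TrainConfig


def _check_finite(value: float, term: str, epoch: int):
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {term} loss ({value}) at epoch {epoch}; aborting"
        )


def train(cases, gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
          loss_w: LossWeights = LossWeights(), cfg: TrainConfig = TrainConfig(),
          norm: NormalizationSpec = NormalizationSpec(),
          checkpoint_dir=None) -> TrainResult:
    """Adversarial training on paired cases.

    ``cases`` is a list of (cect, ncect) :class:`Volume` pairs (registered).
    Each epoch draws ``patches_per_case`` fresh aligned patch pairs per case
    with an epoch-derived seed, so the patch stream is reproducible.
    """
    if not cases:
        raise ValueError("training requires at least one case")
    with default_dtype(np.dtype(cfg.dtype)):
        return _train_impl(cases, gen_cfg, disc_cfg, loss_w, cfg, norm,
                           checkpoint_dir)


def _train_impl(cases, gen_cfg, disc_cfg, loss_w, cfg, norm, checkpoint_dir):
    rng = np.random.default_rng(cfg.seed)
    g_seed, d_seed = int(rng.integers(2**31)), int(rng.integers(2**31))
    generator = build_generator(gen_cfg, seed=g_seed)
    discriminator = build_discriminator(disc_cfg, seed=d_seed)
    extractor = FeatureExtractor(seed=cfg.extractor_seed)
    g_opt = Adam(generator.parameters(), lr=cfg.initial_lr, betas=cfg.betas)
    d_opt = Adam(discriminator.parameters(), lr=cfg.initial_lr, betas=cfg.betas)

    normed = [
        (normalize_array(c.grid, norm), normalize_array(n.grid, norm))
        for c, n in cases
    ]
    history = []
    for epoch in range(1, cfg.total_epochs + 1):
        lr = lr_at_epoch(epoch, cfg)
        g_opt.lr = d_opt.lr = lr
        sums = {"d": 0.0, "g_adv": 0.0, "g_l1": 0.0, "g_perc": 0.0, "g_total": 0.0}
        n_steps = 0
        epoch_seed = int(np.random.default_rng((cfg.seed, epoch)).integers(2**31))
        order = np.random.default_rng((cfg.seed, epoch, 1)).permutation(len(normed))
        for ci in order:
            cect_n, ncect_n = normed[ci]
            pairs = sample_patches(
                Volume(cect_n), Volume(ncect_n), cfg.patches_per_case,
                gen_cfg.patch_size, seed=epoch_seed + int(ci),
            )
            for pair in pairs:
                x = Tensor(pair.cect_patch[None])
                y = Tensor(pair.ncect_patch[None])

                fake = generator(x)

                # discriminator update on the detached fake
                d_opt.zero_grad()
                real_scores = discriminator(x, y)
                fake_scores_d = discriminator(x, fake.detach())
                d_loss = adversarial_loss_discriminator(real_scores, fake_scores_d)
                _check_finite(d_loss.item(), "discriminator", epoch)
                d_loss.backward()
                d_opt.step()

                # generator update
                g_opt.zero_grad()
                fake_scores_g = discriminator(x, fake)
                adv = adversarial_loss_generator(fake_scores_g)
                l1 = l1_loss(fake, y)
                perc = perceptual_loss(fake, y, extractor)
                g_loss = total_generator_loss(adv, l1, perc, loss_w)
                for term, val in (("adversarial", adv), ("l1", l1),
                                  ("perceptual", perc)):
                    _check_finite(val.item(), term, epoch)
                g_loss.backward()
                g_opt.step()

                sums["d"] += d_loss.item()
                sums["g_adv"] += adv.item()
                sums["g_l1"] += l1.item()
                sums["g_perc"] += perc.item()
                sums["g_total"] += g_loss.item()
                n_steps += 1
        record = {"epoch": epoch, "lr": lr}
        record.update({k: v / n_steps for k, v in sums.items()})
        history.append(record)
        logger.info("epoch %d: %s", epoch, json.dumps(record))
        if checkpoint_dir is not None and cfg.checkpoint_every and (
            epoch % cfg.checkpoint_every == 0
        ):
            save_checkpoint(
                f"{checkpoint_dir}/checkpoint_epoch{epoch:04d}.npz",
                generator, discriminator, g_opt, d_opt, epoch, cfg, history,
            )
    return TrainResult(generator, discriminator, history, cfg)


# -- checkpoints ---------------------------------------------------------------


def config_hash(*cfgs) -> str:
    blob = json.dumps([asdict(c) for c in cfgs], sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(path, generator, discriminator, g_opt, d_opt, epoch,
                    cfg: TrainConfig, history=None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "epoch": int(epoch),
        "train_config": asdict(cfg),
        "generator_config": asdict(generator.cfg),
        "discriminator_config": asdict(discriminator.cfg),
        "config_hash": config_hash(generator.cfg, discriminator.cfg, cfg),
        "history": history or [],
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta, default=list).encode(), dtype=np.uint8)}
    for tag, mod in (("g", generator), ("d", discriminator)):
        for k, v in mod.state_dict().items():
            arrays[f"{tag}::{k}"] = v
    for tag, opt in (("og", g_opt), ("od", d_opt)):
        st = opt.state_dict()
        arrays[f"{tag}::scalars"] = np.array([st["t"], st["lr"]])
        for i, m in enumerate(st["m"]):
            arrays[f"{tag}::m{i}"] = m
        for i, v in enumerate(st["v"]):
            arrays[f"{tag}::v{i}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Restore generator/discriminator (weights + configs) from a checkpoint."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"unsupported checkpoint version {meta.get('version')} in {path}"
        )
    g_cfg = meta["generator_config"]
    d_cfg = meta["discriminator_config"]
    for c in (g_cfg, d_cfg):
        for k, v in c.items():
            if isinstance(v, list):
                c[k] = tuple(v)
    generator = build_generator(GeneratorConfig(**g_cfg))
    discriminator = build_discriminator(DiscriminatorConfig(**d_cfg))
    generator.load_state_dict(
        {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("g::")}
    )
    discriminator.load_state_dict(
        {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("d::")}
    )
    return generator, discriminator, meta
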