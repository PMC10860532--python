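"""The packaged desk-scale contrast-removal study.

Generates a cohort of paired phantoms, trains the toy-scale GAN on a
seeded 16/4 split, converts the held-out CECTs, and scores contrast
removal: mean absolute HU error inside enhancing organs for the generated
volume versus the unprocessed CECT (both against the true NCECT), plus
whole-volume cosine similarity and MSE.  This is the CPU-scale analogue
of the clinical observation that generated NCECTs cut the mean HU
deviation by an order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import default_clinical_spec, generate_phantom
from .preprocess import NormalizationSpec, split_cases
from .networks import GeneratorConfig, DiscriminatorConfig
from .objectives import LossWeights
from .engine import TrainConfig, train, plan_patches, convert_volume
from .evaluation import cosine_similarity, mse


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale study conditions (see docs/methods.md)."""

    n_cases: int = 20
    n_train: int = 16
    volume_shape: tuple = (64, 64, 32)
    patch_size: tuple = (48, 48, 16)
    epochs: int = 30
    patches_per_case: int = 2
    initial_lr: float = 1e-3
    base_channels: int = 8
    max_channels: int = 32
    overlap: float = 0.5


def run_contrast_removal_study(seed: int, cfg: StudyConfig = StudyConfig()) -> dict:
    """Run the full simulate-train-convert-evaluate loop; returns metrics.

    All randomness derives from ``seed``.  The headline number is
    ``hu_error_reduction_pct``: the percent reduction of mean |HU error|
    inside enhancing organs, generated-vs-true relative to CECT-vs-true.
    """
    cases = []
    for i in range(cfg.n_cases):
        spec = default_clinical_spec(volume_shape=cfg.volume_shape,
                                   seed=(1000 * seed + i) % 2**31)
        ncect, cect, labels = generate_phantom(spec)
        cases.append((cect, ncect, labels))
    train_idx, val_idx = split_cases(cfg.n_cases, cfg.n_train, seed)

    gen_cfg = GeneratorConfig(n_levels=2, base_channels=cfg.base_channels,
                              max_channels=cfg.max_channels,
                              patch_size=cfg.patch_size)
    disc_cfg = DiscriminatorConfig(n_layers=2, base_channels=cfg.base_channels,
                                   max_channels=cfg.max_channels,
                                   patch_size=cfg.patch_size)
    tc = TrainConfig(total_epochs=cfg.epochs, const_lr_epochs=cfg.epochs // 2,
                     initial_lr=cfg.initial_lr,
                     patches_per_case=cfg.patches_per_case, seed=seed)
    result = train([(cases[i][0], cases[i][1]) for i in train_idx],
                   gen_cfg, disc_cfg, LossWeights(), tc)

    norm = NormalizationSpec()
    plan = plan_patches(cfg.volume_shape, cfg.patch_size, cfg.overlap)
    err_gen, err_cect, cos_gen, cos_cect, mse_gen, mse_cect = [], [], [], [], [], []
    for i in val_idx:
        cect, ncect, labels = cases[i]
        generated = convert_volume(result.generator, cect, plan, norm)
        organ = labels.grid != 0  # all six structures enhance
        err_gen.append(float(np.abs(generated.grid - ncect.grid)[organ].mean()))
        err_cect.append(float(np.abs(cect.grid - ncect.grid)[organ].mean()))
        cos_gen.append(cosine_similarity(ncect, generated, norm))
        cos_cect.append(cosine_similarity(ncect, cect, norm))
        mse_gen.append(mse(ncect, generated, norm))
        mse_cect.append(mse(ncect, cect, norm))
    e_gen, e_cect = float(np.mean(err_gen)), float(np.mean(err_cect))
    return {
        "seed": seed,
        "n_train": len(train_idx),
        "n_val": len(val_idx),
        "hu_error_generated": e_gen,
        "hu_error_cect": e_cect,
        "hu_error_ratio": e_gen / e_cect,
        "hu_error_reduction_pct": 100.0 * (1.0 - e_gen / e_cect),
        "cosine_similarity_generated": float(np.mean(cos_gen)),
        "cosine_similarity_cect": float(np.mean(cos_cect)),
        "mse_generated": float(np.mean(mse_gen)),
        "mse_cect": float(np.mean(mse_cect)),
        "final_train_l1": result.history[-1]["g_l1"],
    }
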