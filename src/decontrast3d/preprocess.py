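"""Pair preprocessing: coarse z-alignment, resampling, intensity
normalization and random patch extraction.

The preparation pipeline for paired CECT/NCECT training data is: crop both
scans to their common z-extent, interpolate to a common grid, window and
rescale intensities to [-1, 1], then randomly crop aligned 3D patch pairs.
Deformable registration is deliberately not implemented here — real pairs
must arrive registered (external tooling); simulated pairs are born
registered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

# Default HU window mapped onto [-1, 1]; covers the clinical abdominal range
# (air at -1000 through dense bone) symmetrically around +476 HU midpoint.
DEFAULT_HU_WINDOW = (-1024.0, 1976.0)


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine HU windowing onto the network intensity range [-1, 1]."""

    hu_window: tuple = DEFAULT_HU_WINDOW

    def __post_init__(self):
        lo, hi = self.hu_window
        if not (lo < hi):
            raise ValueError(f"degenerate HU window {self.hu_window}")

    @property
    def low(self):
        return float(self.hu_window[0])

    @property
    def high(self):
        return float(self.hu_window[1])


@dataclass
class PatchPair:
    """An aligned (CECT, NCECT) sub-volume pair cut at the same corner."""

    cect_patch: np.ndarray
    ncect_patch: np.ndarray
    corner: tuple
    size: tuple

    def __post_init__(self):
        if self.cect_patch.shape != self.ncect_patch.shape:
            raise ValueError(
                f"patch shapes differ: {self.cect_patch.shape} vs {self.ncect_patch.shape}"
            )


def coarse_align(cect: Volume, ncect: Volume):
    """Crop both volumes to the intersection of their z world extents.

    x/y are untouched.  Voxels are kept when their z centers fall inside the
    closed intersection interval.  Raises ``ValueError`` when the extents are
    disjoint.
    """
    out = []
    lo_c, hi_c = cect.world_extent(2)
    lo_n, hi_n = ncect.world_extent(2)
    lo, hi = max(lo_c, lo_n), min(hi_c, hi_n)
    if lo > hi:
        raise ValueError(
            f"volumes do not overlap along z: cect [{lo_c}, {hi_c}] mm "
            f"vs ncect [{lo_n}, {hi_n}] mm"
        )
    for v in (cect, ncect):
        z0 = v.origin_mm[2]
        sz = v.spacing_mm[2]
        # voxel centers z0 + i*sz inside [lo, hi]; small eps guards fp round-off
        eps = 1e-9 * max(1.0, abs(hi))
        i0 = int(np.ceil((lo - z0) / sz - eps))
        i1 = int(np.floor((hi - z0) / sz + eps))
        i0 = max(i0, 0)
        i1 = min(i1, v.shape[2] - 1)
        cropped = v.grid[:, :, i0 : i1 + 1]
        origin = (v.origin_mm[0], v.origin_mm[1], z0 + i0 * sz)
        out.append(Volume(cropped, v.spacing_mm, origin))
    return out[0], out[1]


def resample(v: Volume, target_shape, order: int = 1) -> Volume:
    """Interpolate onto a new grid spanning the same world extent.

    Trilinear by default (``order=1``); use ``order=0`` for label maps.  The
    first and last voxel centers of every axis are preserved (endpoint
    convention), so a linear ramp resamples exactly.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 2 for t in target_shape):
        raise ValueError(f"target shape must be >= 2 per axis, got {target_shape}")
    src_shape = v.shape
    if target_shape == tuple(src_shape):
        return v.copy()
    coords = np.meshgrid(
        *[
            np.linspace(0.0, n_src - 1, n_tgt)
            for n_src, n_tgt in zip(src_shape, target_shape)
        ],
        indexing="ij",
    )
    grid = ndimage.map_coordinates(
        np.asarray(v.grid, dtype=np.float64),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    spacing = tuple(
        s * (n_src - 1) / (n_tgt - 1)
        for s, n_src, n_tgt in zip(v.spacing_mm, src_shape, target_shape)
    )
    return Volume(grid.astype(v.grid.dtype, copy=False), spacing, v.origin_mm)


def resample_labels(labels: np.ndarray, target_shape) -> np.ndarray:
    """Nearest-neighbour resampling for integer label grids."""
    v = Volume(labels.astype(np.float64))
    out = resample(v, target_shape, order=0)
    return np.rint(out.grid).astype(labels.dtype)


def normalize(v: Volume, spec: NormalizationSpec = NormalizationSpec()) -> Volume:
    """Clip to the HU window and map it affinely onto [-1, 1]."""
    lo, hi = spec.low, spec.high
    g = np.clip(np.asarray(v.grid, dtype=np.float64), lo, hi)
    g = 2.0 * (g - lo) / (hi - lo) - 1.0
    return Volume(g, v.spacing_mm, v.origin_mm)


def denormalize(v: Volume, spec: NormalizationSpec = NormalizationSpec()) -> Volume:
    """Inverse of :func:`normalize` on in-window values."""
    lo, hi = spec.low, spec.high
    g = (np.asarray(v.grid, dtype=np.float64) + 1.0) / 2.0 * (hi - lo) + lo
    return Volume(g, v.spacing_mm, v.origin_mm)


def normalize_array(a: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    lo, hi = spec.low, spec.high
    return 2.0 * (np.clip(np.asarray(a, dtype=np.float64), lo, hi) - lo) / (hi - lo) - 1.0


def denormalize_array(a: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    lo, hi = spec.low, spec.high
    return (np.asarray(a, dtype=np.float64) + 1.0) / 2.0 * (hi - lo) + lo


def sample_patches(cect: Volume, ncect: Volume, n: int, size, seed: int):
    """Draw ``n`` aligned random patch pairs.

    Corners are uniform over all valid positions and identical for the two
    volumes, so patches are voxel-aligned.  Deterministic given ``seed``.
    """
    size = tuple(int(s) for s in size)
    if cect.shape != ncect.shape:
        raise ValueError(f"volume shapes differ: {cect.shape} vs {ncect.shape}")
    if any(s > d for s, d in zip(size, cect.shape)):
        raise ValueError(f"patch size {size} exceeds volume shape {cect.shape}")
    rng = np.random.default_rng(seed)
    hi = [d - s for d, s in zip(cect.shape, size)]
    pairs = []
    for _ in range(int(n)):
        corner = tuple(int(rng.integers(0, h + 1)) for h in hi)
        sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
        pairs.append(
            PatchPair(
                cect_patch=np.array(cect.grid[sl]),
                ncect_patch=np.array(ncect.grid[sl]),
                corner=corner,
                size=size,
            )
        )
    return pairs


def split_cases(n_cases: int, n_train: int, seed: int):
    """Seeded random train/validation split over case indices.

    Returns ``(train_idx, val_idx)``; the canonical study split is 16/4
    out of 20 paired cases.
    """
    if n_train > n_cases:
        raise ValueError(f"n_train {n_train} exceeds n_cases {n_cases}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cases)
    return sorted(int(i) for i in perm[:n_train]), sorted(int(i) for i in perm[n_train:])
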