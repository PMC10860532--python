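"""Registered CECT/NCECT phantom pairs with known contrast ground truth.

The simulator paints simple organ shapes (axis-aligned ellipsoids, one
z-aligned tube for the esophagus and one for the great vessels) into a soft
tissue body on an air background, draws per-voxel baseline HU from each
organ's Normal(mean, sd), adds a single Gaussian noise field shared between
the pair, and produces the contrast-enhanced volume by adding an
independent Gaussian enhancement field only inside enhancing organs.
Sharing the noise makes iodine enhancement the sole systematic difference
between the pair — exactly the signal a contrast-removal model must learn.

Per-organ statistics default to clinical abdominal values measured on five
proton patients (true-NCECT baselines; enhancement deltas are the CECT
minus NCECT means, e.g. great vessels 164.1 - 41.2 = 122.9 HU).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume, HU_MIN, HU_MAX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple  # voxel coordinates (x, y, z)
    radii: tuple  # voxels, > 0

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"ellipsoid radii must be positive, got {self.radii}")

    def mask(self, shape):
        idx = np.indices(shape, dtype=np.float64)
        acc = np.zeros(shape)
        for ax in range(3):
            acc += ((idx[ax] - self.center[ax]) / self.radii[ax]) ** 2
        return acc <= 1.0

    def bounds_ok(self, shape):
        return all(
            c - r >= -0.5 and c + r <= s - 0.5
            for c, r, s in zip(self.center, self.radii, shape)
        )


@dataclass(frozen=True)
class Tube:
    """Axis-aligned cylinder (the z axis by default)."""

    center: tuple  # in-plane voxel coordinates of the axis
    radius: float  # voxels, > 0
    span: tuple  # (lo, hi) voxel range along the tube axis, half-open
    axis: int = 2

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"tube radius must be positive, got {self.radius}")
        if self.span[0] >= self.span[1]:
            raise ValueError(f"empty tube span {self.span}")

    def mask(self, shape):
        plane_axes = [a for a in range(3) if a != self.axis]
        idx = np.indices(shape, dtype=np.float64)
        r2 = sum(
            (idx[a] - c) ** 2 for a, c in zip(plane_axes, self.center)
        )
        inside = r2 <= self.radius**2
        along = (idx[self.axis] >= self.span[0]) & (idx[self.axis] < self.span[1])
        return inside & along

    def bounds_ok(self, shape):
        plane_axes = [a for a in range(3) if a != self.axis]
        if not (0 <= self.span[0] and self.span[1] <= shape[self.axis]):
            return False
        return all(
            c - self.radius >= -0.5 and c + self.radius <= shape[a] - 0.5
            for a, c in zip(plane_axes, self.center)
        )


@dataclass(frozen=True)
class OrganSpec:
    name: str
    geometry: object  # Ellipsoid or Tube
    baseline_hu_mean: float
    baseline_hu_sd: float
    enhancement_mean: float = 0.0
    enhancement_sd: float = 0.0
    label_id: int = 1

    def __post_init__(self):
        if self.label_id <= 0:
            raise ValueError(f"label_id must be positive, got {self.label_id}")
        if not (HU_MIN <= self.baseline_hu_mean <= HU_MAX):
            raise ValueError(
                f"baseline HU {self.baseline_hu_mean} outside CT range "
                f"[{HU_MIN}, {HU_MAX}]"
            )
        if self.baseline_hu_sd < 0 or self.enhancement_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple = (64, 64, 32)
    spacing_mm: tuple = (4.0, 4.0, 4.0)
    organs: tuple = ()
    body_hu: float = 35.0
    outside_hu: float = -1000.0
    noise_sd: float = 3.0
    deform_amplitude_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.deform_amplitude_mm < 0:
            raise ValueError("deform_amplitude_mm must be non-negative")
        ids = [o.label_id for o in self.organs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate organ label ids: {ids}")
        for o in self.organs:
            if not o.geometry.bounds_ok(self.volume_shape):
                raise ValueError(
                    f"organ '{o.name}' geometry extends outside grid "
                    f"{self.volume_shape}"
                )


@dataclass
class LabelMap:
    grid: np.ndarray
    label_names: dict

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        present = set(int(l) for l in np.unique(self.grid)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {missing} present in grid but unnamed")

    def mask(self, label_id: int) -> np.ndarray:
        return self.grid == label_id


# Per-structure clinical statistics: (true-NCECT mean, SD; CECT mean, SD), HU.
CLINICAL_STATS = {
    "esophagus": (14.6, 11.1, 27.8, 12.2),
    "great_vessels": (41.2, 6.7, 164.1, 44.2),
    "heart": (22.1, 3.2, 112.4, 43.6),
    "left_kidney": (20.1, 7.1, 83.4, 41.8),
    "right_kidney": (21.0, 8.6, 92.4, 44.6),
    "liver": (46.8, 11.8, 73.1, 23.3),
}

# Organ layout in fractional grid coordinates (scaled by volume_shape).
_LAYOUT = {
    "liver": ("ellipsoid", (0.30, 0.30, 0.55), (0.20, 0.17, 0.28)),
    "heart": ("ellipsoid", (0.70, 0.25, 0.70), (0.13, 0.11, 0.18)),
    "left_kidney": ("ellipsoid", (0.72, 0.72, 0.30), (0.09, 0.08, 0.15)),
    "right_kidney": ("ellipsoid", (0.25, 0.72, 0.30), (0.09, 0.08, 0.15)),
    "great_vessels": ("tube", (0.50, 0.62), 0.050, (0.05, 0.95)),
    "esophagus": ("tube", (0.50, 0.45), 0.033, (0.05, 0.95)),
}


def default_clinical_spec(volume_shape=(64, 64, 32), spacing_mm=(4.0, 4.0, 4.0),
                        seed: int = 0) -> PhantomSpec:
    """Six-organ abdominal phantom parameterized by the clinical statistics.

    Baseline HU per organ is the true-NCECT column; the enhancement mean is
    the CECT-minus-NCECT difference of the printed means.  The enhancement
    SD is chosen so the simulated CECT voxel SD reproduces the printed CECT
    SD: sd_enh = sqrt(max(sd_cect^2 - sd_ncect^2, 0)) (variance additivity
    of the independent enhancement field).
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    if any(s < 32 for s in volume_shape):
        raise ValueError(f"volume_shape must be >= 32 per axis, got {volume_shape}")
    organs = []
    for label_id, (name, (m_n, s_n, m_c, s_c)) in enumerate(CLINICAL_STATS.items(), 1):
        kind = _LAYOUT[name]
        if kind[0] == "ellipsoid":
            _, c, r = kind
            geo = Ellipsoid(
                center=tuple(ci * (si - 1) for ci, si in zip(c, volume_shape)),
                radii=tuple(ri * si for ri, si in zip(r, volume_shape)),
            )
        else:
            _, c, r, span = kind
            geo = Tube(
                center=(c[0] * (volume_shape[0] - 1), c[1] * (volume_shape[1] - 1)),
                radius=r * volume_shape[0],
                span=(span[0] * volume_shape[2], span[1] * volume_shape[2]),
            )
        organs.append(
            OrganSpec(
                name=name,
                geometry=geo,
                baseline_hu_mean=m_n,
                baseline_hu_sd=s_n,
                enhancement_mean=round(m_c - m_n, 1),
                enhancement_sd=float(np.sqrt(max(s_c**2 - s_n**2, 0.0))),
                label_id=label_id,
            )
        )
    return PhantomSpec(volume_shape=volume_shape, spacing_mm=spacing_mm,
                       organs=tuple(organs), seed=seed)


def _body_mask(shape):
    """Elliptical soft tissue cylinder along z filling most of the grid."""
    nx, ny, nz = shape
    idx = np.indices(shape, dtype=np.float64)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    return ((idx[0] - cx) / (0.48 * nx)) ** 2 + (
        (idx[1] - cy) / (0.48 * ny)
    ) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Simulate a registered (NCECT, CECT) pair and its organ label map.

    Deterministic given ``spec.seed``; identical spec+seed gives bitwise
    identical volumes.  Overlapping organ geometries are resolved
    later-listed-wins with a logged warning.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)

    ncect = np.full(shape, spec.outside_hu, dtype=np.float64)
    ncect[_body_mask(shape)] = spec.body_hu
    labels = np.zeros(shape, dtype=np.int16)
    enhancement = np.zeros(shape)
    names = {}

    for organ in spec.organs:
        m = organ.geometry.mask(shape)
        overlap = m & (labels != 0)
        if overlap.any():
            prior = sorted(names[l] for l in np.unique(labels[overlap]) if l != 0)
            logger.warning(
                "organ '%s' overlaps %s on %d voxels; later-listed organ wins",
                organ.name, prior, int(overlap.sum()),
            )
        n_vox = int(m.sum())
        ncect[m] = rng.normal(organ.baseline_hu_mean, organ.baseline_hu_sd, n_vox)
        if organ.enhancement_mean != 0.0:
            enhancement[m] = rng.normal(
                organ.enhancement_mean, organ.enhancement_sd, n_vox
            )
        else:
            enhancement[m] = 0.0
        labels[m] = organ.label_id
        names[organ.label_id] = organ.name

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, shape)
        ncect = ncect + noise  # shared between the pair
    cect = ncect + enhancement

    ncect = np.clip(ncect, HU_MIN, HU_MAX)
    cect = np.clip(cect, HU_MIN, HU_MAX)

    ncect_v = Volume(ncect, spec.spacing_mm)
    cect_v = Volume(cect, spec.spacing_mm)
    if spec.deform_amplitude_mm > 0:
        # emulate inter-scan tissue motion on the contrast scan only
        cect_v = apply_deformation(
            cect_v, spec.deform_amplitude_mm, seed=spec.seed + 1
        )
    return ncect_v, cect_v, LabelMap(labels, names)


def displacement_field(shape, amplitude_mm: float, seed: int, smooth_vox: float = 4.0):
    """Smooth random 3-vector field (mm) with max |displacement| <= amplitude."""
    rng = np.random.default_rng(seed)
    field_ = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), smooth_vox)
         for _ in range(3)]
    )
    mag = np.sqrt((field_**2).sum(axis=0)).max()
    if mag > 0:
        field_ *= amplitude_mm / mag
    return field_


def apply_deformation(v: Volume, amplitude_mm: float, seed: int) -> Volume:
    """Warp a volume by a smooth random displacement field (trilinear)."""
    if amplitude_mm < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude_mm}")
    if amplitude_mm == 0:
        return v.copy()
    disp_mm = displacement_field(v.shape, amplitude_mm, seed)
    idx = np.indices(v.shape, dtype=np.float64)
    for ax in range(3):
        idx[ax] += disp_mm[ax] / v.spacing_mm[ax]
    warped = ndimage.map_coordinates(
        np.asarray(v.grid, dtype=np.float64), idx, order=1, mode="nearest"
    )
    return Volume(warped, v.spacing_mm, v.origin_mm)


# -- YAML (de)serialization ----------------------------------------------------


def spec_to_dict(spec: PhantomSpec) -> dict:
    organs = []
    for o in spec.organs:
        g = o.geometry
        if isinstance(g, Ellipsoid):
            geo = {"type": "ellipsoid", "center": list(g.center),
                   "radii": list(g.radii)}
        else:
            geo = {"type": "tube", "center": list(g.center), "radius": g.radius,
                   "span": list(g.span), "axis": g.axis}
        organs.append({
            "name": o.name, "geometry": geo,
            "baseline_hu_mean": o.baseline_hu_mean,
            "baseline_hu_sd": o.baseline_hu_sd,
            "enhancement_mean": o.enhancement_mean,
            "enhancement_sd": o.enhancement_sd,
            "label_id": o.label_id,
        })
    return {
        "volume_shape": list(spec.volume_shape),
        "spacing_mm": list(spec.spacing_mm),
        "body_hu": spec.body_hu, "outside_hu": spec.outside_hu,
        "noise_sd": spec.noise_sd,
        "deform_amplitude_mm": spec.deform_amplitude_mm,
        "seed": spec.seed, "organs": organs,
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    organs = []
    for o in d.get("organs", []):
        g = o["geometry"]
        if g["type"] == "ellipsoid":
            geo = Ellipsoid(tuple(g["center"]), tuple(g["radii"]))
        elif g["type"] == "tube":
            geo = Tube(tuple(g["center"]), float(g["radius"]),
                       tuple(g["span"]), int(g.get("axis", 2)))
        else:
            raise ValueError(f"unknown geometry type '{g['type']}'")
        organs.append(OrganSpec(
            name=o["name"], geometry=geo,
            baseline_hu_mean=float(o["baseline_hu_mean"]),
            baseline_hu_sd=float(o["baseline_hu_sd"]),
            enhancement_mean=float(o.get("enhancement_mean", 0.0)),
            enhancement_sd=float(o.get("enhancement_sd", 0.0)),
            label_id=int(o["label_id"]),
        ))
    return PhantomSpec(
        volume_shape=tuple(d.get("volume_shape", (64, 64, 32))),
        spacing_mm=tuple(d.get("spacing_mm", (4.0, 4.0, 4.0))),
        organs=tuple(organs),
        body_hu=float(d.get("body_hu", 35.0)),
        outside_hu=float(d.get("outside_hu", -1000.0)),
        noise_sd=float(d.get("noise_sd", 3.0)),
        deform_amplitude_mm=float(d.get("deform_amplitude_mm", 0.0)),
        seed=int(d.get("seed", 0)),
    )


def save_spec(spec: PhantomSpec, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> PhantomSpec:
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
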