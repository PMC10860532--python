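"""Evaluation: global similarity metrics, per-structure HU / mass-density
reports, and water-equivalent path length (WEPL) range surrogates.

Cosine similarity and MSE are computed on intensities rescaled to [0, 1]
over the HU window (reported MSE values on the 1e-3 scale imply normalized
units).  Mass density comes from a monotone piecewise-linear HU-to-density
calibration curve of the kind used by treatment planning systems; relative
stopping power is approximated by relative mass density, so proton-range
comparisons are WEPL-depth comparisons, and are labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import Volume
from .preprocess import NormalizationSpec

logger = logging.getLogger(__name__)

# A typical clinical-style HU -> mass density (g/cm^3) curve; replace with a
# site-specific curve when available.  Water anchored at (0 HU, 1.000).
DEFAULT_CURVE_POINTS = (
    (-1000.0, 0.00121),
    (-700.0, 0.30),
    (-98.0, 0.93),
    (0.0, 1.000),
    (60.0, 1.06),
    (300.0, 1.16),
    (1500.0, 1.82),
)

AXIS_DIRECTIONS = {"+x": (0, +1), "-x": (0, -1), "+y": (1, +1),
                   "-y": (1, -1), "+z": (2, +1), "-z": (2, -1)}


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear HU -> mass density map, clamped at the ends."""

    points: tuple = DEFAULT_CURVE_POINTS

    def __post_init__(self):
        if len(self.points) == 0:
            raise ValueError("calibration curve is empty")
        hu = np.array([p[0] for p in self.points])
        rho = np.array([p[1] for p in self.points])
        if not np.all(np.diff(hu) > 0):
            raise ValueError("curve HU breakpoints must be strictly increasing")
        if not np.all(np.diff(rho) >= 0):
            raise ValueError("curve densities must be non-decreasing")

    @property
    def hu(self):
        return np.array([p[0] for p in self.points], dtype=np.float64)

    @property
    def rho(self):
        return np.array([p[1] for p in self.points], dtype=np.float64)


def default_calibration_curve() -> CalibrationCurve:
    return CalibrationCurve()


def hu_to_density(hu, curve: CalibrationCurve = CalibrationCurve()):
    """Interpolate mass density (g/cm^3); constant beyond the curve ends."""
    return np.interp(np.asarray(hu, dtype=np.float64), curve.hu, curve.rho)


@dataclass(frozen=True)
class BeamSpec:
    """An axis-aligned beam through the isocenter.

    ``direction`` is one of +x/-x/+y/-y/+z/-z; the beam line takes its
    transverse position from the isocenter and starts at the entry index
    along the beam axis.
    """

    entry: tuple
    direction: str
    isocenter: tuple

    def __post_init__(self):
        if self.direction not in AXIS_DIRECTIONS:
            raise ValueError(f"direction must be one of {list(AXIS_DIRECTIONS)}")

    def validate_for(self, shape):
        for name, vox in (("entry", self.entry), ("isocenter", self.isocenter)):
            if not all(0 <= v < s for v, s in zip(vox, shape)):
                raise ValueError(f"beam {name} {vox} outside volume {shape}")


def _metric_normalize(v: Volume, norm: NormalizationSpec) -> np.ndarray:
    lo, hi = norm.low, norm.high
    return (np.clip(np.asarray(v.grid, dtype=np.float64), lo, hi) - lo) / (hi - lo)


def cosine_similarity(y: Volume, y_hat: Volume,
                      norm: NormalizationSpec = NormalizationSpec()) -> float:
    """Cosine of the angle between the flattened intensity vectors, in [-1, 1]."""
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    a = _metric_normalize(y, norm).ravel()
    b = _metric_normalize(y_hat, norm).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm volume")
    return float(a @ b / (na * nb))


def mse(y: Volume, y_hat: Volume,
        norm: NormalizationSpec = NormalizationSpec()) -> float:
    """Mean squared difference of normalized ([0, 1]) intensities."""
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    d = _metric_normalize(y, norm) - _metric_normalize(y_hat, norm)
    return float(np.mean(d**2))


def structure_stats(v: Volume, labels) -> pd.DataFrame:
    """Per-structure voxelwise mean and population SD of HU.

    Empty masks yield a flagged row (NaN stats, n_voxels = 0) rather than a
    fabricated value.
    """
    grid = np.asarray(v.grid, dtype=np.float64)
    if labels.grid.shape != grid.shape:
        raise ValueError(
            f"label shape {labels.grid.shape} does not match volume {grid.shape}"
        )
    rows = []
    for label_id, name in sorted(labels.label_names.items()):
        mask = labels.grid == label_id
        n = int(mask.sum())
        if n == 0:
            logger.warning("structure '%s' has an empty mask", name)
            rows.append({"structure": name, "label_id": label_id,
                         "n_voxels": 0, "mean_hu": np.nan, "sd_hu": np.nan})
            continue
        vals = grid[mask]
        rows.append({
            "structure": name, "label_id": label_id, "n_voxels": n,
            "mean_hu": float(vals.mean()), "sd_hu": float(vals.std()),
        })
    return pd.DataFrame(rows)


def density_diff_percent(test: Volume, ref: Volume, labels,
                         curve: CalibrationCurve = CalibrationCurve()) -> pd.DataFrame:
    """Per-structure mean/SD of voxelwise |rho_test - rho_ref| / rho_ref * 100."""
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    rho_t = hu_to_density(test.grid, curve)
    rho_r = hu_to_density(ref.grid, curve)
    rows = []
    for label_id, name in sorted(labels.label_names.items()):
        mask = labels.grid == label_id
        rt, rr = rho_t[mask], rho_r[mask]
        ok = rr != 0
        if not np.all(ok):
            logger.warning(
                "structure '%s': %d zero-density reference voxels excluded",
                name, int((~ok).sum()),
            )
        rt, rr = rt[ok], rr[ok]
        if rr.size == 0:
            rows.append({"structure": name, "label_id": label_id,
                         "mean_pct": np.nan, "sd_pct": np.nan})
            continue
        pct = np.abs(rt - rr) / rr * 100.0
        rows.append({"structure": name, "label_id": label_id,
                     "mean_pct": float(pct.mean()), "sd_pct": float(pct.std())})
    return pd.DataFrame(rows)


def line_profile(v: Volume, beam: BeamSpec, quantity: str = "hu",
                 curve: CalibrationCurve = CalibrationCurve()):
    """Sample values along the beam axis through the isocenter.

    Returns ``(depths_mm, values)``; depth 0 at the entry voxel center and
    one sample per voxel traversed until the volume boundary.
    """
    beam.validate_for(v.shape)
    axis, step = AXIS_DIRECTIONS[beam.direction]
    idx = list(beam.isocenter)
    start = beam.entry[axis]
    n_axis = v.shape[axis]
    indices = range(start, n_axis) if step > 0 else range(start, -1, -1)
    vals = []
    for i in indices:
        idx[axis] = i
        vals.append(float(v.grid[tuple(idx)]))
    vals = np.array(vals)
    depths = np.arange(len(vals)) * v.spacing_mm[axis]
    if quantity == "hu":
        return depths, vals
    if quantity == "density":
        return depths, hu_to_density(vals, curve)
    raise ValueError(f"unknown quantity '{quantity}' (use 'hu' or 'density')")


def wepl(v: Volume, beam: BeamSpec,
         curve: CalibrationCurve = CalibrationCurve()):
    """Cumulative water-equivalent depth along the beam.

    Each voxel contributes ``rho_rel * step_mm`` where ``rho_rel`` is mass
    density relative to water (the stopping-power surrogate).  Returns
    ``(exit_depths_mm, cumulative_wepl_mm, total_wepl_mm)`` where
    ``exit_depths_mm[k]`` is the geometric depth at the far edge of the
    k-th voxel.
    """
    axis, _ = AXIS_DIRECTIONS[beam.direction]
    step = v.spacing_mm[axis]
    _, hu_vals = line_profile(v, beam, "hu")
    rho_rel = hu_to_density(hu_vals, curve) / 1.000
    cumulative = np.cumsum(rho_rel * step)
    exit_depths = np.arange(1, len(hu_vals) + 1) * step
    return exit_depths, cumulative, float(cumulative[-1])


def depth_at_wepl(v: Volume, beam: BeamSpec, target_wepl: float,
                  curve: CalibrationCurve = CalibrationCurve()) -> float:
    """Geometric depth (mm) at which cumulative WEPL reaches the target."""
    exit_depths, cumulative, total = wepl(v, beam, curve)
    if target_wepl > total:
        raise ValueError(
            f"target WEPL {target_wepl} mm unreachable (total {total:.2f} mm)"
        )
    return float(np.interp(target_wepl, np.concatenate(([0.0], cumulative)),
                           np.concatenate(([0.0], exit_depths))))


def range_shift(a: Volume, b: Volume, beam: BeamSpec,
                curve: CalibrationCurve = CalibrationCurve(),
                target_wepl: float = 50.0, names=("a", "b")) -> float:
    """depth_b(target) - depth_a(target); positive = b's range sits deeper.

    A volume with extra contrast (higher HU, higher density) reaches the
    target WEPL at a shallower geometric depth, giving a negative shift
    relative to the non-contrast volume.
    """
    depths = []
    for v, name in zip((a, b), names):
        try:
            depths.append(depth_at_wepl(v, beam, target_wepl, curve))
        except ValueError as exc:
            raise ValueError(f"volume '{name}': {exc}") from exc
    return depths[1] - depths[0]


DIFF_COLUMNS = ("hu_diff_two_ncect", "hu_diff_cect", "pct_diff_two_ncect",
                "pct_diff_cect")


def aggregate_report(rows) -> dict:
    """Unweighted arithmetic column means, rounded to report precision (2 dp).

    ``rows`` is a DataFrame or list of dicts of per-structure difference
    values; every numeric column is averaged.
    """
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("aggregate_report requires at least one row")
    out = {}
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            out[col] = round(float(df[col].mean()), 2)
    return out


def full_report(generated: Volume, true_ncect: Volume, cect: Volume, labels,
                curve: CalibrationCurve = CalibrationCurve(),
                norm: NormalizationSpec = NormalizationSpec()) -> dict:
    """Per-structure HU and mass-density report plus global metrics.

    Difference convention (single-case reports): per structure, the
    voxelwise mean/SD of |HU_test - HU_ref| and of the absolute relative
    density deviation percent, with the true NCECT as reference for both
    the generated NCECT and the CECT.  SDs are population SDs.
    """
    per = {}
    for tag, vol in (("generated", generated), ("true_ncect", true_ncect),
                     ("cect", cect)):
        per[tag] = structure_stats(vol, labels).set_index("structure")
    rows = []
    for label_id, name in sorted(labels.label_names.items()):
        mask = labels.grid == label_id
        d_gen = np.abs(np.asarray(generated.grid)[mask]
                       - np.asarray(true_ncect.grid)[mask])
        d_cect = np.abs(np.asarray(cect.grid)[mask]
                        - np.asarray(true_ncect.grid)[mask])
        rows.append({
            "structure": name,
            "n_voxels": int(mask.sum()),
            "mean_hu_generated": per["generated"].loc[name, "mean_hu"],
            "sd_hu_generated": per["generated"].loc[name, "sd_hu"],
            "mean_hu_true": per["true_ncect"].loc[name, "mean_hu"],
            "sd_hu_true": per["true_ncect"].loc[name, "sd_hu"],
            "mean_hu_cect": per["cect"].loc[name, "mean_hu"],
            "sd_hu_cect": per["cect"].loc[name, "sd_hu"],
            "hu_diff_two_ncect": float(d_gen.mean()),
            "hu_diff_two_ncect_sd": float(d_gen.std()),
            "hu_diff_cect": float(d_cect.mean()),
            "hu_diff_cect_sd": float(d_cect.std()),
        })
    table = pd.DataFrame(rows).set_index("structure")
    dd_gen = density_diff_percent(generated, true_ncect, labels, curve)
    dd_cect = density_diff_percent(cect, true_ncect, labels, curve)
    table["pct_diff_two_ncect"] = dd_gen.set_index("structure")["mean_pct"]
    table["pct_diff_two_ncect_sd"] = dd_gen.set_index("structure")["sd_pct"]
    table["pct_diff_cect"] = dd_cect.set_index("structure")["mean_pct"]
    table["pct_diff_cect_sd"] = dd_cect.set_index("structure")["sd_pct"]
    summary = aggregate_report(table[list(DIFF_COLUMNS)].reset_index(drop=True))
    return {
        "per_structure": table.reset_index(),
        "summary": summary,
        "cosine_similarity": cosine_similarity(true_ncect, generated, norm),
        "cosine_similarity_cect": cosine_similarity(true_ncect, cect, norm),
        "mse": mse(true_ncect, generated, norm),
        "mse_cect": mse(true_ncect, cect, norm),
        "metadata": {
            "intensity_scale": f"[0,1] over HU window {norm.hu_window}",
            "sd_convention": "population (divide by n)",
            "range_convention": "WEPL-depth comparison (not dose fall-off)",
        },
    }
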