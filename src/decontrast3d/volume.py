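"""The 3D image container and NIfTI / DICOM-series I/O.

A :class:`Volume` is a 3D grid of Hounsfield units with voxel spacing and a
world origin, axis order ``(x, y, z)`` with ``z`` the slice axis.  World
position of voxel index ``i`` along an axis is ``origin + i * spacing``
(0-based voxel-center convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class Volume:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Voxel values (HU for CT volumes, or normalized intensities).
    spacing_mm : tuple of 3 floats
        Voxel spacing along (x, y, z), strictly positive.
    origin_mm : tuple of 3 floats
        World coordinate of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self):
        return self.grid.shape

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.spacing_mm, self.origin_mm)

    def clip_hu(self) -> "Volume":
        """Clamp values to the CT dynamic range [-1024, 3071] HU."""
        return Volume(np.clip(self.grid, HU_MIN, HU_MAX), self.spacing_mm, self.origin_mm)

    def world_extent(self, axis: int):
        """(first, last) voxel-center world coordinates along an axis."""
        lo = self.origin_mm[axis]
        return lo, lo + (self.shape[axis] - 1) * self.spacing_mm[axis]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff


def read_volume(path) -> Volume:
    """Read a NIfTI file into a :class:`Volume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation.  Raises a ``ValueError`` naming the path on malformed input.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        grid = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:  # nibabel raises various types on corrupt files
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {grid.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(grid, spacing, origin)


def write_volume(v: Volume, path) -> None:
    """Write a :class:`Volume` to NIfTI (.nii or .nii.gz); lossless in float32."""
    img = nib.Nifti1Image(np.asarray(v.grid, dtype=np.float32), v.affine())
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, os.fspath(path))


def read_dicom_series(directory) -> Volume:
    """Collapse a single-series DICOM directory into a Volume.

    Slices are sorted by ImagePositionPatient along the slice normal; pixel
    values are rescaled to HU via RescaleSlope/Intercept.  Only axial,
    uniformly spaced series are supported.
    """
    import pydicom

    directory = os.fspath(directory)
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise ValueError(f"cannot parse DICOM file {f}: {exc}") from exc
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no image slices found in {directory}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    stack = np.stack(
        [s.pixel_array.T.astype(np.float32) * slope + intercept for s in slices],
        axis=-1,
    )
    ps = [float(x) for x in slices[0].PixelSpacing]
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(
            slices[0].ImagePositionPatient[2]
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = tuple(float(x) for x in slices[0].ImagePositionPatient)
    return Volume(stack, (ps[1], ps[0], abs(dz)), origin)
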