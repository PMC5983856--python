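"""Volume and mask containers plus NIfTI/NRRD round-trip I/O.

Arrays are indexed ``(slice, row, col)`` — i.e. (z, y, x) with 0-based
indices. The world position of a voxel center is ``origin + index * spacing``
(millimetres); phantoms are axis-aligned, so direction cosines are carried
through file round trips but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, FormatError, ShapeError

#: HU range of a calibrated 12-bit CT reconstruction.
HU_MIN = -1024.0
HU_MAX = 3071.0

#: Spacing/origin agreement tolerance for grid alignment, in mm.
ALIGN_TOL_MM = 1e-6


@dataclass
class CTVolume:
    """A 3-D attenuation grid in Hounsfield units with voxel spacing metadata.

    Parameters
    ----------
    values
        3-D array indexed (slice, row, col); finite HU.
    spacing
        Voxel size in mm per axis, same order as the array axes.
    origin
        World-space position (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError(f"volume must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoxelMask:
    """A binary grid aligned to a :class:`CTVolume` (1 = nodule)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ShapeError(f"mask must be 3-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq}")
        self.values = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())


def _split_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise FormatError(f"unrecognized volume extension on {path!s} "
                      "(expected .nii, .nii.gz or .nrrd)")


def _write_nifti(values: np.ndarray, spacing, origin, path: Path) -> None:
    # nibabel's canonical axis order is (x, y, z); our arrays are (z, y, x).
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    affine[:3, 3] = [origin[2], origin[1], origin[0]]
    img = nib.Nifti1Image(np.transpose(values, (2, 1, 0)), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path!s}: expected a 3-D payload, got {data.ndim}-D")
    values = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    trans = img.affine[:3, 3]
    origin = (float(trans[2]), float(trans[1]), float(trans[0]))
    return values, spacing, origin


def _write_nrrd(values: np.ndarray, spacing, origin, path: Path) -> None:
    img = sitk.GetImageFromArray(values)  # SimpleITK takes (z, y, x) arrays
    img.SetSpacing(tuple(spacing[::-1]))
    img.SetOrigin(tuple(origin[::-1]))
    sitk.WriteImage(img, str(path))


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ShapeError(f"{path!s}: expected a 3-D payload, got {img.GetDimension()}-D")
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    return values, spacing, origin


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = Path(path)
    fmt = _split_format(path)
    values = volume.values.astype(np.float32, copy=False)
    if fmt == "nifti":
        _write_nifti(values, volume.spacing, volume.origin, path)
    else:
        _write_nrrd(values, volume.spacing, volume.origin, path)


def read_volume(path: str | Path) -> CTVolume:
    """Read a volume; write→read round trips preserve values bit-exactly
    and spacing to 1e-6 mm."""
    path = Path(path)
    fmt = _split_format(path)
    values, spacing, origin = _read_nifti(path) if fmt == "nifti" else _read_nrrd(path)
    return CTVolume(values=values, spacing=spacing, origin=origin)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a binary mask as an unsigned 8-bit labeled image (1 = nodule)."""
    path = Path(path)
    fmt = _split_format(path)
    values = mask.values.astype(np.uint8, copy=False)
    if fmt == "nifti":
        _write_nifti(values, mask.spacing, mask.origin, path)
    else:
        _write_nrrd(values, mask.spacing, mask.origin, path)


def read_mask(path: str | Path) -> VoxelMask:
    """Read a binary mask written by :func:`write_mask`."""
    path = Path(path)
    fmt = _split_format(path)
    values, spacing, origin = _read_nifti(path) if fmt == "nifti" else _read_nrrd(path)
    return VoxelMask(values=(np.asarray(values) > 0).astype(np.uint8),
                     spacing=spacing, origin=origin)


def check_aligned(volume: CTVolume | VoxelMask, mask: VoxelMask) -> None:
    """Assert that two grids coincide: equal shapes, spacing and origin
    agreeing within ``ALIGN_TOL_MM``. Raises :class:`AlignmentError` naming
    the first differing field."""
    if volume.shape != mask.shape:
        raise AlignmentError(f"shape mismatch: {volume.shape} vs {mask.shape}")
    for name in ("spacing", "origin"):
        a = np.asarray(getattr(volume, name))
        b = np.asarray(getattr(mask, name))
        if np.any(np.abs(a - b) > ALIGN_TOL_MM):
            raise AlignmentError(f"{name} mismatch: {tuple(a)} vs {tuple(b)}")


def voxel_centers_mm(shape, spacing, origin) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World-space (mm) coordinate grids of voxel centers, one array per axis."""
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] for i in range(3)]
    return tuple(np.meshgrid(*axes, indexing="ij"))
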