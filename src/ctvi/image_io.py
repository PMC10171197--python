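"""Volumes, masks, reading/writing and grid preprocessing.

Axis convention
---------------
Arrays are indexed ``(x, y, z)`` where axis 0 (``x``) is the left-right
(laterality) axis, axis 1 (``y``) anterior-posterior and axis 2 (``z``)
inferior-superior.  All geometric quantities (seed spacing, interpolation
distances, super-voxel centers) are computed in physical millimetres so
they are invariant to the voxel grid; the world coordinate of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.

Images read from disk are reoriented to a single canonical axis-aligned
orientation (closest-to-LPS) so that the laterality axis is always axis 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "median_denoise",
    "intersect_masks",
]

log = logging.getLogger(__name__)

#: tolerance for spacing equality between grids, in mm
SPACING_TOL = 1e-6
#: tolerance for origin equality between grids, in mm
ORIGIN_TOL = 1e-3


@dataclass
class Volume:
    """A scalar field on a regular 3D grid with physical metadata.

    Parameters
    ----------
    data
        Voxel values, shape ``(nx, ny, nz)``; must be finite.
    spacing
        Voxel size in mm per axis, strictly positive.
    origin
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grid_compatible(self, other: "Volume") -> bool:
        """Same shape, spacing within 1e-6 mm and origin within 1e-3 mm."""
        return (
            self.shape == other.shape
            and all(
                abs(a - b) <= SPACING_TOL for a, b in zip(self.spacing, other.spacing)
            )
            and all(abs(a - b) <= ORIGIN_TOL for a, b in zip(self.origin, other.origin))
        )

    def require_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.grid_compatible(other):
            raise ValueError(
                f"{what} are not grid-compatible: "
                f"{self.shape}@{self.spacing} vs {other.shape}@{other.spacing}"
            )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) as 1D arrays."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new volume on the same grid carrying `data`."""
        return Volume(data, self.spacing, self.origin)


@dataclass
class BinaryMask(Volume):
    """A {0,1} voxel mask on the same kind of grid as :class:`Volume`."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            self.data = (np.asarray(self.data) > 0.5).astype(np.uint8)
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask values must be 0 or 1")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if self.n_foreground == 0:
            raise ValueError("mask is empty (no foreground voxels)")


# ---------------------------------------------------------------------------
# File I/O (NIfTI, MetaImage, NRRD via SimpleITK)
# ---------------------------------------------------------------------------


def _to_canonical(img: sitk.Image) -> sitk.Image:
    """Reorient to the closest axis-aligned LPS orientation.

    Guarantees the in-memory laterality axis is the array's axis 0 regardless
    of how the file was stored.
    """
    return sitk.DICOMOrient(img, "LPS")


def read_volume(path: str | Path, kind: str = "ct") -> Volume | BinaryMask:
    """Read a medical-image volume (``.nii/.nii.gz/.mha/.mhd/.nrrd``).

    Parameters
    ----------
    path
        Image file with spacing metadata.
    kind
        ``"ct"`` or ``"ventilation"`` return a :class:`Volume`; ``"mask"``
        binarizes at 0.5 and returns a :class:`BinaryMask`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if kind not in ("ct", "ventilation", "mask"):
        raise ValueError(f"unknown kind {kind!r}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"volume must be 3D: {path} is {img.GetDimension()}D")
    img = _to_canonical(img)
    # sitk arrays come back (z, y, x); transpose to the (x, y, z) convention
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if any(s <= 0 for s in spacing):
        raise ValueError(f"missing or invalid spacing metadata in {path}")
    if kind == "mask":
        return BinaryMask(data > 0.5, spacing, origin)
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume; masks are stored as unsigned 8-bit."""
    data = v.data
    if isinstance(v, BinaryMask):
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, str(Path(path)))


def _to_sitk(v: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    return img


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def resample_isotropic(
    v: Volume, target_spacing_mm: float = 2.0, is_mask: bool | None = None
) -> Volume | BinaryMask:
    """Resample to an isotropic grid (default 2 mm).

    Intensity volumes are interpolated trilinearly, masks nearest-neighbour
    (and re-binarized).  A volume already on the target grid is returned
    unchanged.  The world extent is preserved to within one voxel.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if is_mask is None:
        is_mask = isinstance(v, BinaryMask)
    if all(abs(s - target_spacing_mm) <= SPACING_TOL for s in v.spacing):
        return v
    new_size = [
        max(1, int(round(n * s / target_spacing_mm)))
        for n, s in zip(v.shape, v.spacing)
    ]
    img = _to_sitk(v)
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        v.origin,
        (target_spacing_mm,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    data = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    spacing = (target_spacing_mm,) * 3
    if is_mask:
        return BinaryMask(data > 0.5, spacing, v.origin)
    return Volume(np.asarray(data, dtype=np.float64), spacing, v.origin)


def median_denoise(v: Volume, window_voxels: int = 5) -> Volume:
    """3D median filter with a cubic window (default 5 voxels per side).

    Edges use nearest-replication so lung-border statistics are not diluted
    by out-of-volume zeros.  A window of 1 is the identity.
    """
    if window_voxels < 1 or window_voxels % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window_voxels}")
    if window_voxels == 1:
        return v
    out = ndimage.median_filter(v.data, size=window_voxels, mode="nearest")
    return v.with_data(out)


def intersect_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two grid-compatible masks."""
    a.require_grid(b, "masks")
    out = (a.data & b.data).astype(np.uint8)
    if out.sum() == 0:
        log.warning("mask intersection is empty")
    return BinaryMask(out, a.spacing, a.origin)
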