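"""Deformation-field based comparator ventilation images.

Two conventional estimators computed from an externally supplied
deformation field mapping the exhale CT to the inhale CT:

* density change (``CTVI_HU``): each exhale voxel at x is mapped to
  x' = x + u(x) in the inhale image and the ventilation is the air-volume
  change implied by the HU change,

      Vent(x) = -1000 (HU_ex(x) - HU_in(x')) / (HU_ex(x) (HU_in(x') + 1000))

* volume change (``CTVI_Jac``): the local volume expansion of the mapping,

      Vent(x) = det(I + grad u(x)) - 1.

The registration itself is out of scope; the field is an input.  Both raw
images can be passed through the super-voxel interpolation pipeline
(:func:`supervoxel_average`) to obtain their super-voxel-smoothed variants
(``CTVI_SVHU``, ``CTVI_SVJac``) and, with a SPECT image as input, ``VI_SV``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, Volume
from .supervoxel import SuperVoxelMap, compute_label_stats
from .ctvi_core import VentilationImage, interpolate_ventilation, smooth

__all__ = ["DeformationField", "ctvi_hu", "ctvi_jac", "supervoxel_average"]

log = logging.getLogger(__name__)

#: denominator guard for the density-change formula, HU^2 units
DENOM_EPS = 1e-6


@dataclass
class DeformationField:
    """Per-voxel displacement u(x) in mm on the exhale grid.

    Convention: world position x' = x + u(x), pull-back sampling of the
    inhale image.  ``u`` has shape ``(nx, ny, nz, 3)``.
    """

    u: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("deformation field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("deformation field has non-finite components")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]


def ctvi_hu(
    ct_ex: Volume,
    ct_in: Volume,
    dvf: DeformationField,
    mask: BinaryMask,
) -> tuple[VentilationImage, dict]:
    """Density-change ventilation on the exhale grid.

    The inhale CT is sampled trilinearly at the mapped positions; mapped
    positions outside the inhale volume use the nearest border value and
    are counted.  Voxels whose denominator magnitude falls below
    ``DENOM_EPS`` HU^2 are set to 0 and counted.  Returns the image and a
    dict of guard counts.
    """
    ct_ex.require_grid(mask, "exhale CT and mask")
    if dvf.shape != ct_ex.shape:
        raise ValueError("deformation field must live on the exhale grid")
    spacing_in = np.asarray(ct_in.spacing)
    origin_in = np.asarray(ct_in.origin)

    idx = np.indices(ct_ex.shape, dtype=np.float64)
    world = idx * np.asarray(ct_ex.spacing).reshape(3, 1, 1, 1) + np.asarray(
        ct_ex.origin
    ).reshape(3, 1, 1, 1)
    mapped = world + np.moveaxis(dvf.u, -1, 0)
    cont_idx = (mapped - origin_in.reshape(3, 1, 1, 1)) / spacing_in.reshape(3, 1, 1, 1)

    upper = np.array(ct_in.shape).reshape(3, 1, 1, 1) - 1
    oob = ((cont_idx < 0) | (cont_idx > upper)).any(axis=0) & (mask.data > 0)
    n_oob = int(oob.sum())
    if n_oob:
        log.warning("%d mask voxels map outside the inhale volume", n_oob)

    hu_in = ndimage.map_coordinates(
        np.asarray(ct_in.data, dtype=np.float64), cont_idx, order=1, mode="nearest"
    )
    hu_ex = np.asarray(ct_ex.data, dtype=np.float64)

    denom = hu_ex * (hu_in + 1000.0)
    singular = np.abs(denom) < DENOM_EPS
    n_singular = int((singular & (mask.data > 0)).sum())
    vent = np.zeros(ct_ex.shape, dtype=np.float64)
    ok = (mask.data > 0) & ~singular
    vent[ok] = -1000.0 * (hu_ex[ok] - hu_in[ok]) / denom[ok]
    img = VentilationImage(vent, ct_ex.spacing, ct_ex.origin, provenance="HU")
    return img, {"n_singular": n_singular, "n_out_of_volume": n_oob}


def ctvi_jac(dvf: DeformationField, mask: BinaryMask) -> VentilationImage:
    """Jacobian-determinant ventilation: det(I + grad u) - 1 inside the mask.

    Spatial derivatives use central differences in mm (one-sided at the
    volume boundary).
    """
    if dvf.shape != mask.shape:
        raise ValueError("deformation field must live on the mask grid")
    spacing = dvf.spacing
    # jac[i][j] = d u_i / d x_j
    jac = [
        [np.gradient(dvf.u[..., i], spacing[j], axis=j) for j in range(3)]
        for i in range(3)
    ]
    for i in range(3):
        jac[i][i] = jac[i][i] + 1.0
    a, b, c = jac[0]
    d, e, f = jac[1]
    g, h, i_ = jac[2]
    det = a * (e * i_ - f * h) - b * (d * i_ - f * g) + c * (d * h - e * g)
    vent = np.where(mask.data > 0, det - 1.0, 0.0)
    return VentilationImage(vent, dvf.spacing, dvf.origin, provenance="Jac")


def supervoxel_average(
    v: Volume,
    svm: SuperVoxelMap,
    mask: BinaryMask,
    sides: list[tuple[BinaryMask, np.ndarray]] | None = None,
    sigma_voxels: float = 1.0,
    kernel_halfwidth_voxels: int = 3,
    provenance: str = "SV",
) -> VentilationImage:
    """Super-voxel-smoothed variant of a ventilation (or SPECT) image.

    Computes the mean of ``v`` per super-voxel and feeds those means
    through the same Gaussian-distance interpolation and smoothing as
    CTVI_SVD — without the density gate, since the values already are
    ventilation.  With a SPECT image as input this produces ``VI_SV``.
    """
    if v.shape != svm.labels.shape:
        raise ValueError("image and super-voxel map grids differ")
    compute_label_stats(svm, v, which="vent_mean")
    values = svm.vent_mean
    out = interpolate_ventilation(svm, values, mask, sides=sides)
    img = smooth(out, mask, sigma_voxels, kernel_halfwidth_voxels)
    return VentilationImage(img.data, v.spacing, v.origin, provenance=provenance)
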