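"""CTVI_SVD: a surrogate ventilation image from a single exhale CT.

The method rests on the empirical coupling between regional lung density
and regional ventilation: poorly ventilated (e.g. emphysematous) lung is
more air-like, hence darker on CT.  The pipeline is

1. resample the exhale CT to 2 mm isotropic and median-denoise it,
2. cluster the lung into super-voxels (SLIC),
3. convert HU to density, ``rho = (HU + 1000) / 1000``, and take the mean
   density ``D_mean`` per super-voxel,
4. zero super-voxels with ``D_mean > 0.6`` — denser than the -400 HU
   parenchyma bound, i.e. consolidation or tumour rather than aerated lung,
5. interpolate the gated ``D_mean`` values from the super-voxel geometric
   centers to every lung voxel with Gaussian distance weights
   ``w_ij = exp(-(r_ij / r_mean)^2)``, per lung side (ipsilateral only),
6. smooth with a 3D Gaussian inside the mask.

Interpolation weights are row-normalized so that every voxel's weights sum
to one; this makes the interpolation exact on constant fields and keeps the
output scale independent of the number of super-voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import BinaryMask, Volume
from .supervoxel import SlicParams, SuperVoxelMap, compute_label_stats, run_slic
from . import image_io

__all__ = [
    "CtviParams",
    "CtviSvdResult",
    "InterpolationWeights",
    "VentilationImage",
    "hu_to_density",
    "gate_supervoxels",
    "build_weights",
    "interpolate_ventilation",
    "smooth",
    "split_lungs",
    "split_labels_by_side",
    "manual_defect_correction",
    "run_ctvi_svd",
]

log = logging.getLogger(__name__)


@dataclass
class VentilationImage(Volume):
    """A ventilation-valued volume: finite inside the lung mask, 0 outside.

    ``provenance`` records which estimator produced it (``"SVD"``, ``"HU"``,
    ``"Jac"``, ``"SVHU"``, ``"SVJac"``, ``"VI_SV"`` or ``"reference"``).
    """

    provenance: str = "SVD"

    @classmethod
    def from_volume(cls, v: Volume, provenance: str) -> "VentilationImage":
        return cls(v.data, v.spacing, v.origin, provenance=provenance)


def display_scaled(v: VentilationImage, mask: BinaryMask) -> VentilationImage:
    """Visualization-only rescale: 99th percentile (and above) -> 100, min -> 0.

    Never applied before metric computation.
    """
    vals = v.data[mask.data > 0]
    lo, hi = vals.min(), np.percentile(vals, 99)
    out = np.zeros_like(v.data, dtype=np.float64)
    if hi > lo:
        out[mask.data > 0] = np.clip((vals - lo) / (hi - lo) * 100.0, 0, 100)
    return VentilationImage(out, v.spacing, v.origin, provenance=v.provenance)


def hu_to_density(v: Volume) -> Volume:
    """Convert CT numbers to density: rho = (HU + 1000) / 1000.

    -1000 HU (air) -> 0, 0 HU (water) -> 1.
    """
    return v.with_data((np.asarray(v.data, dtype=np.float64) + 1000.0) / 1000.0)


def gate_supervoxels(svm: SuperVoxelMap, threshold: float = 0.6) -> np.ndarray:
    """Source ventilation values per label: D_mean, zeroed where too dense.

    Labels with mean density strictly greater than ``threshold`` (0.6, the
    density of -400 HU — the upper bound of aerated parenchyma) get source
    value 0 but remain interpolation sources, so tumour regions pull their
    surroundings down instead of inheriting neighbouring values.
    """
    if svm.d_mean is None:
        raise ValueError("compute_label_stats with a density volume first")
    values = svm.d_mean.copy()
    values[svm.d_mean > threshold] = 0.0
    return values


# ---------------------------------------------------------------------------
# Gaussian-distance interpolation from super-voxel centers
# ---------------------------------------------------------------------------


@dataclass
class InterpolationWeights:
    """Row-normalized Gaussian weights from lung voxels to SV centers.

    Raw weights are ``w_ij = exp(-(r_ij / r_mean)^2)`` with ``r_ij`` the
    voxel-to-center distance in mm and ``r_mean`` the mean nearest-neighbour
    center distance of the ipsilateral labels.  Rows are normalized to sum
    to one when applied.  The dense matrix is materialized only on demand
    (tests / small problems); :meth:`apply` streams over voxel chunks.
    """

    voxel_coords_mm: np.ndarray  # (n, 3)
    centers_mm: np.ndarray  # (K, 3)
    r_mean: float
    label_ids: np.ndarray  # (K,) original label numbers
    row_normalized: bool = True
    _chunk: int = field(default=8192, repr=False)

    def _raw_chunk(self, sl: slice) -> np.ndarray:
        d = self.voxel_coords_mm[sl, None, :] - self.centers_mm[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        # subtract the row-min exponent: cancels under normalization and
        # avoids underflow for voxels far from every center
        e = r2 / (self.r_mean**2)
        return np.exp(-(e - e.min(axis=1, keepdims=True))), e

    def matrix(self) -> np.ndarray:
        """Dense (n_voxels, K) weight matrix (row-normalized)."""
        rows = []
        for start in range(0, self.voxel_coords_mm.shape[0], self._chunk):
            sl = slice(start, start + self._chunk)
            d = self.voxel_coords_mm[sl, None, :] - self.centers_mm[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            w = np.exp(-r2 / (self.r_mean**2))
            if self.row_normalized:
                w = w / w.sum(axis=1, keepdims=True)
            rows.append(w)
        return np.concatenate(rows, axis=0)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Interpolated value per voxel: ``V = W V_sup`` with unit row sums."""
        values = np.asarray(values, dtype=np.float64)
        out = np.empty(self.voxel_coords_mm.shape[0])
        for start in range(0, out.shape[0], self._chunk):
            sl = slice(start, start + self._chunk)
            w, _ = self._raw_chunk(sl)
            out[sl] = (w @ values) / w.sum(axis=1)
        return out


def build_weights(
    svm: SuperVoxelMap, mask_side: BinaryMask, label_ids: np.ndarray | None = None
) -> InterpolationWeights:
    """Interpolation weights for the voxels of one lung side.

    ``label_ids`` restricts the sources to the ipsilateral labels (default:
    all labels of ``svm``).  Requires at least two source labels so that
    ``r_mean`` is defined; the single-label case is handled by the caller as
    a constant image.
    """
    if svm.centers is None:
        compute_label_stats(svm)
    if label_ids is None:
        label_ids = np.arange(1, svm.n_labels + 1)
    label_ids = np.asarray(label_ids)
    if label_ids.size < 2:
        raise ValueError("need >= 2 labels on a lung side for interpolation")
    centers = svm.centers[label_ids - 1]
    tree = cKDTree(centers)
    d, _ = tree.query(centers, k=2)
    r_mean = float(d[:, 1].mean())
    if r_mean <= 0:
        raise ValueError("degenerate super-voxel centers (r_mean = 0)")
    coords = np.argwhere(mask_side.data > 0)
    world = coords * np.asarray(mask_side.spacing) + np.asarray(mask_side.origin)
    return InterpolationWeights(world, centers, r_mean, label_ids)


def interpolate_ventilation(
    svm: SuperVoxelMap,
    source_values: np.ndarray,
    mask: BinaryMask,
    sides: list[tuple[BinaryMask, np.ndarray]] | None = None,
) -> VentilationImage:
    """Interpolate per-label source values to every lung voxel.

    ``sides`` is a list of ``(side_mask, label_ids)`` pairs; each voxel is
    interpolated only from the ipsilateral labels.  Default: one side
    covering the whole mask with all labels.  Outside the mask the image
    is 0.  A single-label side degenerates to a constant image of that
    label's value (logged).
    """
    if svm.labels.shape != mask.shape:
        raise ValueError("super-voxel map and mask grids differ")
    if sides is None:
        sides = [(mask, np.arange(1, svm.n_labels + 1))]
    out = np.zeros(mask.shape, dtype=np.float64)
    for side_mask, label_ids in sides:
        label_ids = np.asarray(label_ids)
        sel = side_mask.data > 0
        if not sel.any():
            continue
        if label_ids.size == 0:
            log.warning("lung side with no super-voxel; left at 0")
            continue
        if label_ids.size == 1:
            log.warning("single-label lung side: constant image")
            out[sel] = source_values[label_ids[0] - 1]
            continue
        w = build_weights(svm, side_mask, label_ids)
        out[sel] = w.apply(source_values[label_ids - 1])
    return VentilationImage(out, mask.spacing, mask.origin, provenance="SVD")


def smooth(
    v: Volume,
    mask: BinaryMask,
    sigma_voxels: float = 1.0,
    kernel_halfwidth_voxels: int = 3,
    provenance: str | None = None,
) -> VentilationImage:
    """Mask-aware 3D Gaussian smoothing.

    The kernel extends ``kernel_halfwidth_voxels`` voxels (default 3) with
    standard deviation ``sigma_voxels`` (default 1).  Values are
    renormalized by the smoothed mask so the lung border is not diluted by
    the zeros outside; constant fields are preserved exactly.
    """
    if kernel_halfwidth_voxels <= 0:
        raise ValueError("kernel half-width must be positive")
    if sigma_voxels <= 0:
        raise ValueError("sigma must be positive")
    m = (mask.data > 0).astype(np.float64)
    truncate = kernel_halfwidth_voxels / sigma_voxels
    num = ndimage.gaussian_filter(v.data * m, sigma_voxels, truncate=truncate)
    den = ndimage.gaussian_filter(m, sigma_voxels, truncate=truncate)
    out = np.zeros_like(num)
    inside = m > 0
    out[inside] = num[inside] / den[inside]
    prov = provenance or getattr(v, "provenance", "SVD")
    return VentilationImage(out, v.spacing, v.origin, provenance=prov)


# ---------------------------------------------------------------------------
# Lung-side handling
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def split_lungs(mask: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Split a lung mask into (left, right) by laterality (axis 0).

    The two largest 26-connected components become the lungs; any smaller
    components are attached to the nearer lung.  A single fused component is
    split at the sagittal plane through the mask centroid (logged).
    """
    mask.require_nonempty()
    comp, ncomp = ndimage.label(mask.data, structure=_STRUCT_26)
    if ncomp == 1:
        log.info("fused lung mask: splitting at the mid-sagittal centroid plane")
        cx = np.argwhere(mask.data > 0)[:, 0].mean()
        a = mask.data.copy()
        b = mask.data.copy()
        xs = np.arange(mask.shape[0])
        a[xs > cx, :, :] = 0
        b[xs <= cx, :, :] = 0
        left, right = a, b
    else:
        sizes = np.bincount(comp.ravel())[1:]
        order = np.argsort(sizes)[::-1] + 1
        main = order[:2]
        cents = ndimage.center_of_mass(mask.data, comp, main)
        # lower x = left by the canonical orientation
        if cents[0][0] > cents[1][0]:
            main = main[::-1]
            cents = cents[::-1]
        left = (comp == main[0]).astype(np.uint8)
        right = (comp == main[1]).astype(np.uint8)
        for lab in order[2:]:
            c = ndimage.center_of_mass(comp == lab)
            d0 = np.linalg.norm(np.subtract(c, cents[0]) * mask.spacing)
            d1 = np.linalg.norm(np.subtract(c, cents[1]) * mask.spacing)
            if d0 <= d1:
                left |= (comp == lab).astype(np.uint8)
            else:
                right |= (comp == lab).astype(np.uint8)
    lm = BinaryMask(left, mask.spacing, mask.origin)
    rm = BinaryMask(right, mask.spacing, mask.origin)
    if lm.n_foreground == 0 or rm.n_foreground == 0:
        raise ValueError("lung split produced an empty side")
    return lm, rm


def split_labels_by_side(
    svm: SuperVoxelMap, left: BinaryMask, right: BinaryMask
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each label to the side holding the majority of its voxels."""
    k = svm.n_labels
    in_left = np.bincount(
        svm.labels[(left.data > 0) & (svm.labels > 0)], minlength=k + 1
    )[1:]
    in_right = np.bincount(
        svm.labels[(right.data > 0) & (svm.labels > 0)], minlength=k + 1
    )[1:]
    ids = np.arange(1, k + 1)
    return ids[in_left >= in_right], ids[in_right > in_left]


def manual_defect_correction(
    v_presmooth: VentilationImage,
    defect_mask: BinaryMask,
    lung_mask: BinaryMask,
    value: float = 0.0,
    sigma_voxels: float = 1.0,
    kernel_halfwidth_voxels: int = 3,
) -> VentilationImage:
    """Overwrite a contoured defect region with a low value and re-smooth.

    Meant to fix falsely high values over dense defective regions the
    density gate missed; applied to the pre-smoothing image, after which
    the smoothing stage is re-run.
    """
    v_presmooth.require_grid(defect_mask, "image and defect mask")
    corrected = v_presmooth.data.copy()
    corrected[defect_mask.data > 0] = value
    cv = VentilationImage(
        corrected, v_presmooth.spacing, v_presmooth.origin,
        provenance=v_presmooth.provenance,
    )
    return smooth(cv, lung_mask, sigma_voxels, kernel_halfwidth_voxels)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class CtviParams:
    """End-to-end pipeline parameters (defaults are the study conditions)."""

    slic: SlicParams = field(default_factory=SlicParams)
    gate_threshold: float = 0.6  # density of -400 HU, the parenchyma bound
    target_spacing_mm: float = 2.0
    median_window: int = 5
    sigma_voxels: float = 1.0
    kernel_halfwidth_voxels: int = 3
    resample: bool = True
    denoise: bool = True


@dataclass
class CtviSvdResult:
    """Pipeline output: final image plus intermediates for inspection."""

    image: VentilationImage
    presmooth: VentilationImage
    svm: SuperVoxelMap
    mask: BinaryMask
    left: BinaryMask
    right: BinaryMask
    left_labels: np.ndarray
    right_labels: np.ndarray
    source_values: np.ndarray
    n_gated: int
    params: CtviParams

    def with_defect_correction(
        self, defect_mask: BinaryMask, value: float = 0.0
    ) -> VentilationImage:
        return manual_defect_correction(
            self.presmooth, defect_mask, self.mask, value,
            self.params.sigma_voxels, self.params.kernel_halfwidth_voxels,
        )


def run_ctvi_svd(
    ct_ex: Volume,
    mask: BinaryMask,
    params: CtviParams | None = None,
    svm: SuperVoxelMap | None = None,
) -> CtviSvdResult:
    """Run the full CTVI_SVD pipeline on an exhale CT and its lung mask.

    Deterministic: two runs on identical input are bit-identical.  A
    precomputed super-voxel map may be passed to skip the SLIC stage (it
    must live on the preprocessed grid).
    """
    params = params or CtviParams()
    mask.require_nonempty()
    ct_ex.require_grid(mask, "CT and mask")

    if params.resample:
        ct = image_io.resample_isotropic(ct_ex, params.target_spacing_mm, is_mask=False)
        msk = image_io.resample_isotropic(mask, params.target_spacing_mm, is_mask=True)
    else:
        ct, msk = ct_ex, mask
    if params.denoise:
        ct = image_io.median_denoise(ct, params.median_window)
    msk.require_nonempty()

    if svm is None:
        svm = run_slic(ct, msk, params.slic)
    density = hu_to_density(ct)
    compute_label_stats(svm, density, which="d_mean")
    values = gate_supervoxels(svm, params.gate_threshold)
    n_gated = int((svm.d_mean > params.gate_threshold).sum())

    left, right = split_lungs(msk)
    lids, rids = split_labels_by_side(svm, left, right)
    presmooth = interpolate_ventilation(
        svm, values, msk, sides=[(left, lids), (right, rids)]
    )
    image = smooth(
        presmooth, msk, params.sigma_voxels, params.kernel_halfwidth_voxels
    )
    return CtviSvdResult(
        image=image, presmooth=presmooth, svm=svm, mask=msk,
        left=left, right=right, left_labels=lids, right_labels=rids,
        source_values=values, n_gated=n_gated, params=params,
    )
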