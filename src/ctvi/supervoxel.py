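"""Spacing-aware 3D SLIC super-voxel clustering restricted to a lung mask.

The clustering is a local k-means in the joint intensity-space domain.  A
voxel is compared with a candidate cluster center through

    D = sqrt(d_c^2 + (d_s / S)^2 * m^2)

where ``d_c`` is the HU difference to the cluster's mean HU, ``d_s`` the
Euclidean distance in mm to the cluster center, ``S`` the seed sampling
interval (converted to mm) and ``m`` the compactness weight.  ``m`` may be a
fixed number or ``"adaptive"``, in which case each cluster's weight is the
maximum ``|d_c|`` observed in that cluster during the previous iteration
(the SLIC-zero scheme), removing the free parameter.

Seeds are laid on a regular grid of interval ``S = (N / K_init)^(1/3)``
voxels over the lung bounding box (``N`` = lung voxel count), dropped when
outside the mask, and each retained seed is moved to the lowest-gradient
voxel in its in-mask 3x3x3 neighbourhood so that no seed starts on an edge
or a noisy voxel.  The whole procedure is deterministic: ties in the
assignment go to the lower label id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import BinaryMask, Volume

__all__ = [
    "SlicParams",
    "SuperVoxelMap",
    "initialize_seeds",
    "slic_assign",
    "enforce_connectivity",
    "compute_label_stats",
    "run_slic",
]

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SlicParams:
    """SLIC tuning parameters.

    ``k_init`` is the requested number of super-voxels (the number actually
    extracted, ``K_final``, is smaller after out-of-mask seed dropping and
    connectivity enforcement).  ``compactness_m`` is either a number in HU
    or ``"adaptive"`` for the per-cluster SLIC-zero scheme.
    ``convergence_tol`` is the mean center displacement (mm) below which
    iteration stops.
    """

    k_init: int = 1500
    max_iters: int = 10
    compactness_m: float | str = "adaptive"
    convergence_tol: float = 0.1
    min_size_voxels: int | None = None  # default (S^3)/4, set at run time

    def __post_init__(self) -> None:
        if self.k_init < 1:
            raise ValueError("k_init must be >= 1")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")
        if isinstance(self.compactness_m, str) and self.compactness_m != "adaptive":
            raise ValueError("compactness_m must be a number or 'adaptive'")


@dataclass
class SuperVoxelMap:
    """Label field plus per-label statistics.

    ``labels`` is 0 outside the lung and ``1..K_final`` inside; label voxel
    sets partition the mask.  Statistics (filled by
    :func:`compute_label_stats`) are indexed by ``label - 1``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    voxel_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    centers: np.ndarray | None = None  # (K, 3) world mm
    d_mean: np.ndarray | None = None
    vent_mean: np.ndarray | None = None
    r_mean: float | None = None
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.voxel_count is None:
            self.voxel_count = np.bincount(
                self.labels.ravel(), minlength=self.n_labels + 1
            )[1:]

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def mask_array(self) -> np.ndarray:
        return self.labels > 0

    def check_partition(self, mask: BinaryMask) -> None:
        """Raise unless labels partition the mask exactly."""
        inside = self.labels[mask.data > 0]
        outside = self.labels[mask.data == 0]
        if inside.size and inside.min() < 1:
            raise AssertionError("mask voxels with label 0")
        if outside.size and outside.max() > 0:
            raise AssertionError("labels outside the mask")
        k = self.n_labels
        counts = np.bincount(self.labels.ravel(), minlength=k + 1)[1:]
        if (counts == 0).any():
            raise AssertionError("label ids are not contiguous")
        if counts.sum() != mask.n_foreground:
            raise AssertionError("label counts do not sum to mask size")


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def _hu_gradient(hu: np.ndarray, spacing) -> np.ndarray:
    """Sum of absolute central differences of HU along the three axes."""
    g = np.zeros_like(hu, dtype=np.float64)
    for ax in range(3):
        g += np.abs(np.gradient(hu, spacing[ax], axis=ax))
    return g


def seed_interval_voxels(n_mask_voxels: int, k_init: int) -> float:
    """Seed sampling interval S = (N / K_init)^(1/3) in voxel units."""
    return float(max(1.0, (n_mask_voxels / k_init) ** (1.0 / 3.0)))


def initialize_seeds(
    ct: Volume, mask: BinaryMask, p: SlicParams
) -> tuple[np.ndarray, np.ndarray]:
    """Place seeds on a regular grid over the mask bounding box.

    Returns ``(positions, hu)`` where positions are integer voxel indices,
    shape ``(K, 3)``.  Seeds outside the mask are dropped; each kept seed is
    moved to the minimum-gradient in-mask voxel of its 3x3x3 neighbourhood
    (ties keep the original position).
    """
    mask.require_nonempty()
    ct.require_grid(mask, "CT and mask")
    n = mask.n_foreground
    s = seed_interval_voxels(n, p.k_init)

    idx = np.argwhere(mask.data > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    axes = []
    for a in range(3):
        extent = hi[a] - lo[a] + 1
        count = max(1, int(np.floor(extent / s)))
        # centered grid: offset s/2 keeps seeds away from the bbox faces
        pos = lo[a] + (np.arange(count) + 0.5) * (extent / count)
        axes.append(np.clip(np.floor(pos).astype(int), lo[a], hi[a]))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    keep = mask.data[grid[:, 0], grid[:, 1], grid[:, 2]] > 0
    seeds = grid[keep]
    if seeds.shape[0] == 0:
        raise ValueError("mask too small to host any seed")

    grad = _hu_gradient(ct.data, ct.spacing)
    shape = np.array(mask.shape)
    perturbed = np.empty_like(seeds)
    for i, s0 in enumerate(seeds):
        lo3 = np.maximum(s0 - 1, 0)
        hi3 = np.minimum(s0 + 2, shape)
        sub = tuple(slice(a, b) for a, b in zip(lo3, hi3))
        g = grad[sub].copy()
        g[mask.data[sub] == 0] = np.inf
        orig = tuple(s0 - lo3)
        best = np.unravel_index(np.argmin(g), g.shape)
        if g[best] >= g[orig]:  # tie (or original already minimal) -> keep
            best = orig
        perturbed[i] = lo3 + np.array(best)
    # deduplicate while preserving order (grid+perturbation can collide)
    _, first = np.unique(perturbed, axis=0, return_index=True)
    perturbed = perturbed[np.sort(first)]
    hu = ct.data[perturbed[:, 0], perturbed[:, 1], perturbed[:, 2]].astype(np.float64)
    return perturbed, hu


# ---------------------------------------------------------------------------
# Assignment iterations
# ---------------------------------------------------------------------------


def slic_assign(
    ct: Volume,
    mask: BinaryMask,
    seeds: tuple[np.ndarray, np.ndarray],
    p: SlicParams,
) -> SuperVoxelMap:
    """Iterative local k-means assignment of mask voxels to seeds.

    Each iteration assigns every mask voxel inside a ``2S`` search window of
    a cluster center to the center minimizing ``D`` (lower label wins ties),
    then updates centers to the cluster means of position and HU.  Iteration
    stops when the mean center displacement falls below
    ``p.convergence_tol`` mm.  Mask voxels left outside every search window
    are attached to the spatially nearest center.  Connectivity is then
    enforced and labels renumbered ``1..K_final``.

    The per-iteration sum of squared ``D`` over assigned voxels is recorded
    in ``objective_history`` (non-increasing for fixed compactness).
    """
    positions, seed_hu = seeds
    if positions.shape[0] == 0:
        raise ValueError("need at least one seed")
    spacing = np.asarray(ct.spacing)
    hu = np.asarray(ct.data, dtype=np.float64)
    mdat = mask.data > 0
    n = int(mdat.sum())
    k = positions.shape[0]

    s_vox = seed_interval_voxels(n, p.k_init)
    s_mm = s_vox * float(np.prod(spacing) ** (1.0 / 3.0))
    adaptive = p.compactness_m == "adaptive"
    m_k = np.full(k, 10.0 if adaptive else float(p.compactness_m))

    centers_mm = positions * spacing  # origin-free internal coordinates
    centers_hu = seed_hu.copy()
    shape = np.array(hu.shape)
    hw = int(np.ceil(s_vox))  # half-width of the 2S search window
    labels = np.zeros(hu.shape, dtype=np.int32)
    coords = np.argwhere(mdat) * spacing
    history: list[float] = []

    for _ in range(p.max_iters):
        dist2 = np.full(hu.shape, np.inf)
        labels.fill(0)
        for j in range(k):
            c_vox = centers_mm[j] / spacing
            lo = np.maximum(np.round(c_vox).astype(int) - hw, 0)
            hi = np.minimum(np.round(c_vox).astype(int) + hw + 1, shape)
            if (lo >= hi).any():
                continue
            sub = tuple(slice(a, b) for a, b in zip(lo, hi))
            d_c = hu[sub] - centers_hu[j]
            axes_d2 = [
                ((np.arange(lo[a], hi[a]) * spacing[a]) - centers_mm[j][a]) ** 2
                for a in range(3)
            ]
            d_s2 = (
                axes_d2[0][:, None, None]
                + axes_d2[1][None, :, None]
                + axes_d2[2][None, None, :]
            )
            d2 = d_c * d_c + d_s2 / (s_mm * s_mm) * (m_k[j] * m_k[j])
            sub_dist = dist2[sub]
            sub_lab = labels[sub]
            better = mdat[sub] & (d2 < sub_dist)  # strict: lower label wins
            sub_dist[better] = d2[better]
            sub_lab[better] = j + 1

        history.append(float(dist2[mdat & (labels > 0)].sum()))

        unassigned = mdat & (labels == 0)
        if unassigned.any():
            log.debug("%d voxels outside all search windows", int(unassigned.sum()))
            tree = cKDTree(centers_mm)
            pts = np.argwhere(unassigned) * spacing
            _, nearest = tree.query(pts)
            labels[unassigned] = nearest + 1

        flat = labels[mdat]
        counts = np.bincount(flat, minlength=k + 1)[1:].astype(np.float64)
        live = counts > 0
        new_centers = centers_mm.copy()
        new_hu = centers_hu.copy()
        for a in range(3):
            sums = np.bincount(flat, weights=coords[:, a], minlength=k + 1)[1:]
            new_centers[live, a] = sums[live] / counts[live]
        hu_sums = np.bincount(flat, weights=hu[mdat], minlength=k + 1)[1:]
        new_hu[live] = hu_sums[live] / counts[live]

        if adaptive:
            dc_abs = np.abs(hu[mdat] - centers_hu[flat - 1])
            m_new = np.zeros(k)
            np.maximum.at(m_new, flat - 1, dc_abs)
            m_k[live] = np.maximum(m_new[live], 1.0)

        disp = float(np.linalg.norm(new_centers - centers_mm, axis=1).mean())
        centers_mm, centers_hu = new_centers, new_hu
        if disp < p.convergence_tol:
            break

    svm = SuperVoxelMap(
        _relabel(labels), ct.spacing, ct.origin, objective_history=history
    )
    min_size = p.min_size_voxels
    if min_size is None:
        min_size = max(1, int(round(s_vox**3 / 4.0)))
    svm = enforce_connectivity(svm, min_size)
    svm.objective_history = history
    return svm


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels contiguously 1..K keeping 0 as background."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


# ---------------------------------------------------------------------------
# Connectivity enforcement
# ---------------------------------------------------------------------------


def _face_contact(comp_mask: np.ndarray, labels: np.ndarray) -> np.ndarray | None:
    """Labels of face-adjacent voxels around a component, excluding 0."""
    neigh = []
    for ax in range(3):
        for shift in (1, -1):
            rolled = np.roll(comp_mask, shift, axis=ax)
            if shift == 1:
                rolled[tuple(slice(0, 1) if a == ax else slice(None) for a in range(3))] = False
            else:
                rolled[tuple(slice(-1, None) if a == ax else slice(None) for a in range(3))] = False
            sel = rolled & ~comp_mask
            neigh.append(labels[sel])
    vals = np.concatenate(neigh) if neigh else np.array([], dtype=labels.dtype)
    vals = vals[vals > 0]
    return vals if vals.size else None


def enforce_connectivity(svm: SuperVoxelMap, min_size_voxels: int) -> SuperVoxelMap:
    """Merge stray fragments so every label is one 26-connected component.

    Any connected component that is smaller than ``min_size_voxels`` or is
    not its label's largest component is merged into the neighbouring label
    sharing the longest face boundary.  Repeats until stable.
    """
    labels = svm.labels.copy()
    for _ in range(20):
        changed = False
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            # pad one voxel so neighbour lookup inside the crop sees contacts
            sl = tuple(
                slice(max(0, s.start - 1), min(dim, s.stop + 1))
                for s, dim in zip(sl, labels.shape)
            )
            crop = labels[sl]
            comp, ncomp = ndimage.label(crop == lab, structure=_STRUCT_26)
            if ncomp == 0:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            main = int(np.argmax(sizes)) + 1
            for c in range(1, ncomp + 1):
                if c == main and sizes[c - 1] >= min_size_voxels:
                    continue
                if c == main and ncomp == 1 and sizes[c - 1] < min_size_voxels:
                    pass  # undersized singleton label: merge whole label away
                cm = comp == c
                contact = _face_contact(cm, crop)
                if contact is None:
                    continue  # isolated (e.g. the only label in this lung)
                counts = np.bincount(contact, minlength=lab + 1)
                counts[lab] = 0  # never "merge" into itself
                if counts.sum() == 0:
                    continue
                target = int(np.argmax(counts))
                crop[cm] = target
                changed = True
        if not changed:
            break
    return SuperVoxelMap(
        _relabel(labels), svm.spacing, svm.origin,
        objective_history=list(svm.objective_history),
    )


# ---------------------------------------------------------------------------
# Per-label statistics
# ---------------------------------------------------------------------------


def compute_label_stats(
    svm: SuperVoxelMap, value_volume: Volume | None = None, which: str = "d_mean"
) -> SuperVoxelMap:
    """Fill geometric centers, ``r_mean`` and a per-label mean value.

    ``which`` selects the statistic slot: ``"d_mean"`` for mean density of
    the (density-converted) CT, ``"vent_mean"`` for the mean of a reference
    ventilation volume.  ``r_mean`` is the mean over labels of the distance
    from each label's center to its nearest other center, the length scale
    of the Gaussian interpolation.  Modifies and returns ``svm``.
    """
    k = svm.n_labels
    if k == 0:
        raise ValueError("empty super-voxel map")
    flat = svm.labels[svm.labels > 0]
    counts = np.bincount(flat, minlength=k + 1)[1:].astype(np.float64)
    coords = np.argwhere(svm.labels > 0)
    world = coords * np.asarray(svm.spacing) + np.asarray(svm.origin)
    centers = np.empty((k, 3))
    for a in range(3):
        centers[:, a] = (
            np.bincount(flat, weights=world[:, a], minlength=k + 1)[1:] / counts
        )
    svm.centers = centers
    svm.voxel_count = counts.astype(np.int64)
    if k >= 2:
        tree = cKDTree(centers)
        d, _ = tree.query(centers, k=2)
        svm.r_mean = float(d[:, 1].mean())
    else:
        svm.r_mean = None

    if value_volume is not None:
        vals = value_volume.data[svm.labels > 0]
        means = np.bincount(flat, weights=vals, minlength=k + 1)[1:] / counts
        if which == "d_mean":
            svm.d_mean = means
        elif which == "vent_mean":
            svm.vent_mean = means
        else:
            raise ValueError("which must be 'd_mean' or 'vent_mean'")
    return svm


def run_slic(ct: Volume, mask: BinaryMask, p: SlicParams | None = None) -> SuperVoxelMap:
    """Seed, cluster and post-process in one call."""
    p = p or SlicParams()
    seeds = initialize_seeds(ct, mask, p)
    svm = slic_assign(ct, mask, seeds, p)
    return compute_label_stats(svm)
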