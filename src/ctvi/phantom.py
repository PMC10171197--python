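"""Synthetic thorax phantoms for end-to-end pipeline exercise.

A phantom emulates the data the method consumes: an exhale/inhale CT pair
whose lung density is coupled to a known smooth ventilation field, two
ellipsoidal lungs embedded in soft tissue, optional spherical defect
regions (emphysema-like: low HU and low ventilation; consolidation-like:
high HU and low ventilation), a smooth analytic deformation field whose
Jacobian tracks the ventilation field, and a blurred, noisy SPECT-like
reference.

Construction order: the ventilation truth comes first; the exhale CT is
``base_hu + coupling * (vent - vent_mid) + band-limited texture`` plus the
defect HU offsets; the deformation has a single superior-inferior
component ``u_z = alpha * integral_z vent`` so that
``det(I + grad u) - 1 = alpha * vent`` holds (up to discretization); the
inhale CT is the exhale density divided by ``1 + alpha * vent`` pulled
back through the (numerically inverted) deformation.

Everything is reproducible: the same spec and seed give bit-identical
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, Volume
from .dir_ctvi import DeformationField
from .ctvi_core import VentilationImage

__all__ = ["Defect", "PhantomSpec", "PhantomCase", "make_phantom", "make_cohort"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Defect:
    """A spherical defect region (center/radius in world mm).

    ``vent_multiplier`` scales the ventilation field inside the sphere;
    ``hu_offset`` is added to the exhale HU there.  Emphysema-like defects
    use a low multiplier and a negative offset; consolidation-like defects
    a low multiplier and a large positive offset (dense enough to trip the
    0.6 density gate).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    vent_multiplier: float = 0.3
    hu_offset: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic case.

    Defaults give a 96^3 grid at 2 mm with two ellipsoidal lungs, a
    gravity-direction ventilation ramp, moderate density-ventilation
    coupling with band-limited HU texture, an 8 mm FWHM SPECT-like blur
    and 5% multiplicative reference noise.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_semiaxes_mm: tuple[float, float, float] = (32.0, 48.0, 66.0)
    lung_gap_mm: float = 12.0
    base_hu: float = -880.0
    #: fine-grained HU noise (image noise scale): removed by the median
    #: filter and super-voxel averaging
    texture_amplitude_hu: float = 60.0
    texture_correlation_mm: float = 1.5
    #: mesoscale anatomical structure (vessels, septa): survives averaging
    #: and bounds the density-ventilation correlation from above
    structure_amplitude_hu: float = 20.0
    structure_correlation_mm: float = 4.0
    vent_base: float = 0.4
    vent_ramp: float = 0.6
    coupling_hu_per_vent: float = 250.0
    defects: tuple[Defect, ...] = ()
    jacobian_scale: float = 0.15
    spect_fwhm_mm: float = 8.0
    spect_noise_sd: float = 0.05
    soft_tissue_hu: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        # accept lists (e.g. from a JSON spec file)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "spacing_mm", tuple(float(s) for s in self.spacing_mm)
        )
        object.__setattr__(
            self, "lung_semiaxes_mm", tuple(float(a) for a in self.lung_semiaxes_mm)
        )
        object.__setattr__(self, "defects", tuple(self.defects))
        if any(n < 8 for n in self.shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("phantom grid must be at least 8^3 with positive spacing")

    def with_strong_coupling(self) -> "PhantomSpec":
        """Strong density-ventilation coupling, reduced texture.

        The regime in which the surrogate should track the true ventilation
        closely; used for recovery experiments.
        """
        return replace(
            self,
            coupling_hu_per_vent=300.0,
            texture_amplitude_hu=25.0,
            structure_amplitude_hu=8.0,
        )


@dataclass
class PhantomCase:
    ct_ex: Volume
    ct_in: Volume
    lung_mask: BinaryMask
    dvf: DeformationField
    vent_truth: VentilationImage
    spect_like: VentilationImage
    spec: PhantomSpec


def _world_grid(spec: PhantomSpec):
    sp = np.asarray(spec.spacing_mm)
    axes = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    return np.meshgrid(*axes, indexing="ij")


def _lung_mask(spec: PhantomSpec, xw, yw, zw) -> np.ndarray:
    ext = np.array(spec.shape) * np.asarray(spec.spacing_mm)
    a, b, c = spec.lung_semiaxes_mm
    cy, cz = ext[1] / 2.0, ext[2] / 2.0
    cx_l = ext[0] / 2.0 - (a + spec.lung_gap_mm / 2.0)
    cx_r = ext[0] / 2.0 + (a + spec.lung_gap_mm / 2.0)
    left = ((xw - cx_l) / a) ** 2 + ((yw - cy) / b) ** 2 + ((zw - cz) / c) ** 2 <= 1.0
    right = ((xw - cx_r) / a) ** 2 + ((yw - cy) / b) ** 2 + ((zw - cz) / c) ** 2 <= 1.0
    return left | right


def _band_limited_noise(rng, shape, spacing, corr_mm, amplitude) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma = [corr_mm / s for s in spacing]
    sm = ndimage.gaussian_filter(white, sigma)
    sd = sm.std()
    if sd == 0 or amplitude == 0:
        return np.zeros(shape)
    return sm / sd * amplitude


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one synthetic case from its spec (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing_mm)
    xw, yw, zw = _world_grid(spec)
    # `lung` is the anatomical air-filled region; the segmentation mask is
    # eroded one voxel inside the tissue interface, as an intensity-based
    # (region-growing) segmentation would exclude partial-volume voxels
    lung = _lung_mask(spec, xw, yw, zw)
    if not lung.any():
        raise ValueError("lung geometry produces an empty mask")
    mask = ndimage.binary_erosion(lung)
    if not mask.any():
        raise ValueError("lung geometry too thin for a segmentation mask")
    ext_z = spec.shape[2] * sp[2]

    # ventilation truth: gravity-direction ramp, defects multiply it down
    vent_full = spec.vent_base + spec.vent_ramp * (zw / ext_z)
    hu_defect = np.zeros(spec.shape)
    for d in spec.defects:
        ci = tuple(int(round(c / s)) for c, s in zip(d.center_mm, sp))
        if not all(0 <= i < n for i, n in zip(ci, spec.shape)) or not mask[ci]:
            raise ValueError(f"defect center {d.center_mm} mm is outside the lungs")
        r2 = (xw - d.center_mm[0]) ** 2 + (yw - d.center_mm[1]) ** 2 + (
            zw - d.center_mm[2]
        ) ** 2
        inside = r2 <= d.radius_mm**2
        vent_full = np.where(inside, vent_full * d.vent_multiplier, vent_full)
        hu_defect = np.where(inside, hu_defect + d.hu_offset, hu_defect)

    texture = _band_limited_noise(
        rng, spec.shape, sp, spec.texture_correlation_mm, spec.texture_amplitude_hu
    ) + _band_limited_noise(
        rng, spec.shape, sp, spec.structure_correlation_mm, spec.structure_amplitude_hu
    )
    vent_mid = spec.vent_base + spec.vent_ramp / 2.0
    hu_lung = (
        spec.base_hu
        + spec.coupling_hu_per_vent * (vent_full - vent_mid)
        + texture
        + hu_defect
    )
    ct_ex_data = np.where(lung, hu_lung, spec.soft_tissue_hu)
    ct_ex_data = np.clip(ct_ex_data, -1024.0, 200.0)

    # deformation: u_z = alpha * cumulative integral of vent along z, so the
    # Jacobian determinant is 1 + alpha * vent
    alpha = spec.jacobian_scale
    u_z = alpha * np.cumsum(vent_full, axis=2) * sp[2]
    u = np.zeros(spec.shape + (3,))
    u[..., 2] = u_z

    # inhale CT: invert z -> z + u_z by fixed point, divide density by the
    # local volume expansion
    dens_ex = (ct_ex_data + 1000.0) / 1000.0
    iz = np.arange(spec.shape[2], dtype=np.float64)
    zidx = np.broadcast_to(iz, spec.shape).copy()
    base_idx = np.indices(spec.shape, dtype=np.float64)
    for _ in range(4):
        coords = np.stack([base_idx[0], base_idx[1], zidx])
        uz_at = ndimage.map_coordinates(u_z, coords, order=1, mode="nearest")
        zidx = base_idx[2] - uz_at / sp[2]
    coords = np.stack([base_idx[0], base_idx[1], zidx])
    dens_at = ndimage.map_coordinates(dens_ex, coords, order=1, mode="nearest")
    vent_at = ndimage.map_coordinates(vent_full, coords, order=1, mode="nearest")
    dens_in = dens_at / (1.0 + alpha * vent_at)
    ct_in_data = np.clip(dens_in * 1000.0 - 1000.0, -1024.0, 200.0)

    # SPECT-like reference: finite-resolution local average of the in-lung
    # activity (blur renormalized by the blurred mask so the lung border is
    # not diluted by the zero background) with multiplicative noise
    sigma_spect = [spec.spect_fwhm_mm * _FWHM_TO_SIGMA / s for s in sp]
    num = ndimage.gaussian_filter(vent_full * mask, sigma_spect)
    den = ndimage.gaussian_filter(mask.astype(np.float64), sigma_spect)
    blurred = np.zeros(spec.shape)
    blurred[mask] = num[mask] / den[mask]
    noise = 1.0 + spec.spect_noise_sd * rng.standard_normal(spec.shape)
    spect = np.clip(blurred * noise, 0.0, None) * mask

    spacing = tuple(float(s) for s in sp)
    return PhantomCase(
        ct_ex=Volume(ct_ex_data, spacing),
        ct_in=Volume(ct_in_data, spacing),
        lung_mask=BinaryMask(mask, spacing),
        dvf=DeformationField(u, spacing),
        vent_truth=VentilationImage(
            vent_full * mask, spacing, provenance="reference"
        ),
        spect_like=VentilationImage(spect, spacing, provenance="reference"),
        spec=spec,
    )


def default_defects(spec: PhantomSpec) -> tuple[Defect, ...]:
    """One emphysema-like and one consolidation-like defect, one per lung.

    Positions are expressed relative to the spec's lung geometry so they
    stay inside the lungs under moderate jitter.
    """
    ext = np.array(spec.shape) * np.asarray(spec.spacing_mm)
    a = spec.lung_semiaxes_mm[0]
    cx_l = ext[0] / 2.0 - (a + spec.lung_gap_mm / 2.0)
    cx_r = ext[0] / 2.0 + (a + spec.lung_gap_mm / 2.0)
    cy, cz = ext[1] / 2.0, ext[2] / 2.0
    r = min(spec.lung_semiaxes_mm) * 0.45
    return (
        Defect((cx_l, cy, cz + 0.3 * spec.lung_semiaxes_mm[2]), r, 0.3, -60.0),
        Defect((cx_r, cy, cz - 0.3 * spec.lung_semiaxes_mm[2]), r, 0.2, 700.0),
    )


def _lung_centres(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    ext = np.array(spec.shape) * np.asarray(spec.spacing_mm)
    a = spec.lung_semiaxes_mm[0]
    cy, cz = ext[1] / 2.0, ext[2] / 2.0
    left = np.array([ext[0] / 2.0 - (a + spec.lung_gap_mm / 2.0), cy, cz])
    right = np.array([ext[0] / 2.0 + (a + spec.lung_gap_mm / 2.0), cy, cz])
    return left, right


def _recentre_defect(base: PhantomSpec, new: PhantomSpec, d: Defect) -> Defect:
    """Map a defect to the jittered geometry, preserving its relative position."""
    bl, br = _lung_centres(base)
    nl, nr = _lung_centres(new)
    c = np.asarray(d.center_mm)
    src, dst = (bl, nl) if abs(c[0] - bl[0]) <= abs(c[0] - br[0]) else (br, nr)
    rel = (c - src) / np.asarray(base.lung_semiaxes_mm)
    moved = dst + rel * np.asarray(new.lung_semiaxes_mm)
    return replace(d, center_mm=tuple(float(x) for x in moved))


def make_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: float = 1.0,
    seed: int = 0,
) -> list[PhantomCase]:
    """A cohort of ``n`` jittered phantom cases.

    ``jitter`` scales the perturbation ranges (0 disables them): lung
    semi-axes within +/-8%, gap within +/-2 mm, ramp base within +/-0.05,
    defect radii within +/-10%.  Per-case seeds derive from ``seed`` so the
    cohort is reproducible as a whole.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_spec or PhantomSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        draws = rng.uniform(-1.0, 1.0, size=8)
        case_seed = int(ss.generate_state(1)[0] % (2**31))
        if jitter == 0 and i == 0:
            spec = replace(base, seed=base.seed)
        else:
            semi = tuple(
                s * (1.0 + 0.08 * jitter * d)
                for s, d in zip(base.lung_semiaxes_mm, draws[:3])
            )
            spec = replace(
                base,
                lung_semiaxes_mm=semi,
                lung_gap_mm=max(2.0, base.lung_gap_mm + 2.0 * jitter * draws[3]),
                vent_base=base.vent_base + 0.05 * jitter * draws[4],
                seed=case_seed,
            )
            if base.defects:
                moved = tuple(
                    _recentre_defect(base, spec, d) for d in base.defects
                )
                spec = replace(
                    spec,
                    defects=tuple(
                        replace(d, radius_mm=d.radius_mm * (1 + 0.1 * jitter * dr))
                        for d, dr in zip(moved, draws[5 : 5 + len(moved)])
                    ),
                )
        cases.append(make_phantom(spec))
    return cases
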