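# Methods

## The surrogate model

CTVI_SVD treats the mean density of a lung sub-region as a surrogate for
its ventilation. The physical rationale: an aerated lung voxel is a
mixture of air (≈ −1000 HU) and tissue/blood (≈ 0 HU), so its density
`ρ = (HU + 1000)/1000` measures the tissue fraction. Regions that
ventilate poorly because of alveolar destruction (emphysema) contain more
trapped air and are *darker*; within aerated parenchyma, density and
ventilation are therefore positively correlated. The correlation is
empirical and moderate — it breaks down where density rises for reasons
unrelated to airflow (consolidation, tumour, atelectasis), which is why
super-voxels with mean density above 0.6 (the density of −400 HU, the
conventional upper bound of aerated parenchyma) are assigned a ventilation
value of 0 rather than a high one.

Analysing super-voxels instead of voxels is what makes the surrogate
usable: fine-scale CT noise averages out within a cluster of ~10³ voxels,
while the clusters — built by SLIC to follow intensity boundaries — still
respect anatomical structure. The whole-lung image is then recovered by
scattered-data interpolation from the super-voxel centers.

## Pipeline stages and parameters

| stage | parameter | default | why |
|---|---|---|---|
| resample | isotropic spacing | 2 mm | common grid for CT and reference; distances in mm stay meaningful |
| denoise | median window | 5 voxels | robust removal of fine noise without blurring edges |
| SLIC | K_init | 1500 | requested cluster count; extracted K_final is lower |
| SLIC | compactness m | adaptive (SLIC0) | per-cluster m = max observed intensity distance in the previous iteration; removes the free parameter |
| SLIC | max iterations / tol | 10 / 0.1 mm | typical convergence of local k-means |
| connectivity | min component size | S³/4 voxels | standard fragment-merge heuristic |
| gate | density threshold | 0.6 | density of −400 HU; strictly greater fires |
| interpolation | r_mean | mean nearest-neighbour center distance (per lung side) | the kernel length-scale; see below |
| smoothing | kernel | half-width 3 voxels, σ = 1 voxel | final cosmetic smoothing, mask-renormalized |

Geometry is always computed in physical millimetres, so the method is
spacing-invariant and still correct if the resampling stage is skipped.
The SLIC seed interval is `S = (N/K_init)^{1/3}` in voxel units (N = lung
voxel count) — the cube root of the per-seed volume; seeds are laid on a
regular grid over the lung bounding box, dropped outside the mask, and
nudged to the lowest-gradient voxel of their in-mask 3×3×3 neighbourhood
(ties keep the grid position). All ties in cluster assignment go to the
lower label id, making the whole pipeline deterministic — two runs on the
same input are bit-identical.

### Interpolation choices

Two points in the interpolation are genuinely open and were fixed as
follows:

* **Row normalization.** The weights `w_ij = exp(−(r_ij/r_mean)²)` are
  normalized to sum to 1 per voxel. Without normalization the output
  scale would depend on the number of super-voxels, and interpolating a
  constant source field would not return that constant (the property that
  anchors the whole value scale of the image).
* **r_mean.** "Mean distance between super-voxels" is read as the mean
  *nearest-neighbour* center distance among the ipsilateral super-voxels.
  The mean pairwise distance would be of the order of the lung diameter
  and would destroy the locality of the kernel.

Consequences worth knowing: the normalized Gaussian kernel is flat near a
center (neighbouring centers at distance ~r_mean retain weight e⁻¹), so a
single zero-gated super-voxel depresses its region only partially; defect
contrast is spread over roughly one r_mean. Gated super-voxels stay in
the source set with value 0 — removing them would let neighbours bleed
high values into tumour regions. Each lung side is interpolated from its
own super-voxels only, so nothing in the left lung can influence the
right. A lung side with a single super-voxel degenerates to a constant
image (logged). Voxels numerically underflowing all weights are handled by
a per-row max-exponent shift, so the row normalization is always well
defined.

The final Gaussian filter is renormalized by the smoothed mask
(`smooth(v·m)/smooth(m)`), which preserves constants exactly and does not
dilute the lung border with outside zeros. "Kernel size of three voxels"
is implemented as a truncated half-width of 3 voxels with σ = 1 voxel; σ
is exposed as a parameter.

## Comparators

From a supplied deformation field `u(x)` (mm, `x′ = x + u(x)`, pull-back
sampling of the inhale CT):

* density change: `Vent(x) = −1000·(HU_ex(x) − HU_in(x′)) / (HU_ex(x)·(HU_in(x′)+1000))`,
  with denominators below 1e-6 HU² guarded to 0 and counted, and mapped
  positions outside the inhale volume clamped to the border and counted;
* volume change: `Vent(x) = det(I + ∇u(x)) − 1`, gradients by central
  differences in mm (exact for affine fields).

Registration itself is out of scope — the field is an input. Passing any
ventilation-valued image (including SPECT) through the per-super-voxel
mean → interpolation → smoothing chain (without the density gate) yields
the super-voxel-smoothed variants.

## Evaluation

Per case, both images are restricted to the intersection of the CT and
reference lung masks; metrics are the voxel-wise Spearman correlation
(average ranks for ties; undefined below 3 voxels or zero variance) and
the Dice overlap of high-/low-function regions, where "high" is strictly
above the image's own 66th percentile (linear interpolation between order
statistics) over the intersection. Boundary voxels equal to the threshold
go to "low", keeping the split a deterministic partition. The K_init sweep
re-runs the pipeline per requested cluster count and compares per-case
correlations against the reference setting (K_init = 1500) with two-sided
paired t-tests; zero-variance differences leave the t statistic undefined
and are reported as the conservative p = 1.

## The phantom generator

The generator emulates exactly the data the method consumes, with a known
ground truth:

* **Geometry:** two ellipsoidal lungs (semi-axes 32/48/66 mm, 12 mm
  mid-sagittal gap) in soft tissue (+30 HU) on a 96³ grid at 2 mm. The
  lung *mask* is the anatomical region eroded by one voxel, as an
  intensity-based (region-growing) segmentation excludes the
  partial-volume interface; without this, the median filter drags wall
  values into border super-voxels and buries the density signal under a
  segmentation artifact.
* **Ventilation truth:** base 0.4 plus a gravity-direction ramp of 0.6
  across the grid, multiplied down inside spherical defect regions.
* **Exhale CT:** −880 HU base + coupling·(vent − mid) + two-scale texture
  + defect HU offsets, clipped to [−1024, 200]. The texture has a
  fine-grained component (60 HU, 1.5 mm correlation — image noise, which
  the median filter and super-voxel averaging remove) and a mesoscale
  component (20 HU, 4 mm — vessels/septa, which survives averaging and
  bounds the density–ventilation correlation from above). This two-scale
  structure is what makes super-voxel analysis beat voxel-wise analysis
  on the phantom, as it does on real data.
* **Coupling:** default 250 HU per ventilation unit, chosen once so that
  the super-voxel-level density–ventilation Spearman correlation on
  default phantoms sits in the moderate (~0.55–0.6) regime that motivates
  the method. The `with_strong_coupling()` preset (300 HU, reduced
  texture) is the regime where the surrogate should recover the truth
  closely; recovery experiments use it.
* **Deformation:** `u_z = α·∫ vent dz` (α = 0.15), so the Jacobian
  determinant is `1 + α·vent` exactly and the Jacobian comparator can be
  checked against the truth in closed form. The inhale CT is the exhale
  density divided by the local volume expansion, pulled back through the
  numerically inverted map.
* **Reference:** an 8 mm FWHM Gaussian local average of the in-lung truth
  (blur renormalized by the blurred mask — plain blurring of the masked
  field would rank every border voxel low, an artifact of the zero
  background rather than of SPECT resolution) with 5% multiplicative
  noise.
* **Defects:** emphysema-like (ventilation ×0.3, −60 HU) and
  consolidation-like (×0.2, +700 HU — dense enough to trip the 0.6 gate
  under both coupling regimes).

Cohorts jitter the geometry (±8% semi-axes, ±2 mm gap, ±0.05 ramp base,
±10% defect radii) with per-case seeds spawned from a master seed;
everything is bit-reproducible.

What the phantom does **not** model: breathing artifacts in 4DCT,
airway/tracer deposition artifacts in SPECT, lobar anatomy and fissures,
vessel trees with realistic topology, registration error in the supplied
deformation field, and the HU dependence on reconstruction kernels.
Passing tests on phantoms therefore demonstrates the internal consistency
and numerical correctness of the pipeline — not clinical accuracy on
patient data.

## Problem sizes used in the test suite

Unit tests run on toy grids (≤ 32³) against brute-force oracles. The
end-to-end recovery experiments use a 5-case cohort of 96³ phantoms at
2 mm (~10⁵ lung voxels per case) with K_init ∈ {300, 1500, 4000}; these
sizes keep a full suite run in a few minutes on a single CPU while leaving
each lung with several hundred super-voxels at the default K_init.

## Known limitations

* The density–ventilation coupling is assumed positive and monotone;
  diseases that raise density without consolidation-level HU (interstitial
  patterns) are mis-ranked and must be handled by manual defect
  correction (`manual_defect_correction` / `--defect-mask`).
* `K_final/K_init` on phantoms (~0.85) is higher than on patient lungs,
  where anatomy fragments more seed cells; only the monotone growth of
  K_final with K_init is a method property.
* The normalized Gaussian interpolation bounds the dynamic range of the
  output by the range of the super-voxel means; it cannot sharpen
  sub-super-voxel detail.
* Eq.-level behaviour of the comparators is only as good as the supplied
  deformation field; no attempt is made to regularize or validate it
  beyond finiteness and bounds checks.
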