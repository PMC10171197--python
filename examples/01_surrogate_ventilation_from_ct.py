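"""Build a surrogate ventilation image from a single exhale CT.

Generates a small synthetic thorax (two ellipsoidal lungs, a
gravity-direction ventilation gradient coupled to lung density), runs the
super-voxel density pipeline, and compares the surrogate with the known
ventilation truth.
"""

import ctvi

spec = ctvi.PhantomSpec(
    shape=(64, 64, 64), lung_semiaxes_mm=(22.0, 32.0, 44.0), seed=0
).with_strong_coupling()
case = ctvi.make_phantom(spec)
print(f"phantom: {case.lung_mask.n_foreground} lung voxels at 2 mm")

params = ctvi.CtviParams(slic=ctvi.SlicParams(k_init=300))
res = ctvi.run_ctvi_svd(case.ct_ex, case.lung_mask, params)
print(f"super-voxels extracted: {res.svm.n_labels} (requested {params.slic.k_init})")
print(f"mean nearest-neighbour center distance: {res.svm.r_mean:.1f} mm")
print(f"super-voxels gated as too dense (> 0.6): {res.n_gated}")

rho = ctvi.spearman(res.image, case.vent_truth, res.mask)
print(f"Spearman correlation with the true ventilation field: {rho:.3f}")
# Values inside the lung are interpolated mean densities (~0.12 for healthy
# -880 HU parenchyma); a correlation near 1 means the surrogate ranks lung
# regions by ventilation almost as the ground truth does.
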