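"""Manual defect correction and volume file round-trips.

A dense defective region that the density gate misses can be contoured
manually and assigned a low ventilation value before the final smoothing.
Also demonstrates writing/reading volumes (MetaImage here; NIfTI and NRRD
work the same way).
"""

import tempfile
from pathlib import Path

import numpy as np

import ctvi

spec = ctvi.PhantomSpec(
    shape=(64, 64, 64), lung_semiaxes_mm=(22.0, 32.0, 44.0), seed=2
).with_strong_coupling()
case = ctvi.make_phantom(spec)
res = ctvi.run_ctvi_svd(
    case.ct_ex, case.lung_mask, ctvi.CtviParams(slic=ctvi.SlicParams(k_init=300))
)

# contour a spherical "defect" in the left lung and push it to 0
ii, jj, kk = np.indices(res.mask.shape)
ball = ((ii * 2 - 40) ** 2 + (jj * 2 - 64) ** 2 + (kk * 2 - 64) ** 2) <= 12**2
defect = ctvi.BinaryMask(
    ball & (res.mask.data > 0), res.mask.spacing, res.mask.origin
)
corrected = res.with_defect_correction(defect, value=0.0)
before = res.image.data[defect.data > 0].mean()
after = corrected.data[defect.data > 0].mean()
print(f"mean surrogate value in the contour: {before:.3f} -> {after:.3f}")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "ctvi_svd.mha"
    ctvi.write_volume(corrected, path)
    back = ctvi.read_volume(path, kind="ventilation")
    print(f"round-trip max abs difference: "
          f"{np.abs(back.data - corrected.data).max():.2e}")
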