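"""Four-step airway segmentation with ground-truth validation.

Renders a foam phantom at reconstruction-like quality (slight blur plus
noise), segments the airways (bone masking, per-slice iso-thresholds in a
cylinder, 3D connectivity from the trachea, dilated second pass on a
sharpened copy) and compares the recovered air volume to the generator's
bookkeeping.
"""

import numpy as np
from scipy import ndimage

from mosaictomo import segment_airways
from mosaictomo.phantom import make_foam_phantom

ph = make_foam_phantom((96, 128, 128), target_air_fraction=0.5, seed=3)
print(f"phantom: {ph.shape} voxels, realized air fraction "
      f"{ph.meta['realized_air_fraction']:.3f}, ground-truth airspace "
      f"{ph.air_volume_mm3:.6f} mm^3")

rng = np.random.default_rng(0)
vol = ndimage.gaussian_filter(ph.volume.astype(float), 1.0)
vol += 3.0 * rng.standard_normal(vol.shape)

res = segment_airways(vol, ph.voxel_size_um,
                      bone_threshold=3 * ph.mu_tissue)
est_mm3 = res.volume_cm3 * 1e3
err = abs(est_mm3 - ph.air_volume_mm3) / ph.air_volume_mm3
print(f"bone voxels masked: {res.bone_mask.sum()}")
print(f"per-slice thresholds span "
      f"[{res.thresholds.min():.0f}, {res.thresholds.max():.0f}] /m "
      f"(between air ~0 and tissue {ph.mu_tissue:.0f})")
print(f"estimated airway volume: {est_mm3:.6f} mm^3 "
      f"({res.volume_cm3:.3e} cm^3)")
print(f"relative error vs ground truth: {100 * err:.1f}%")
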