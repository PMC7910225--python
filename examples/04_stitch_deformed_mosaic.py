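"""Non-rigid stitching of a slowly deforming 2 x 1 x 2 mosaic.

Runs the full pipeline (simulate, flat-field, retrieve, reconstruct) on a
phantom that creeps during the acquisition, then compares rigid-only
stitching against the non-rigid displacement-field stitcher via the
per-voxel overlap standard-deviation map.
"""

import numpy as np

from mosaictomo.config import desk_scale_config
from mosaictomo.pipeline import run_pipeline, stitch_tiles

cfg = desk_scale_config(seed=1, deformed=True)
res = run_pipeline(cfg)
print(f"simulated {len(res.tiles)} tiles; sample creep "
      f"{cfg.sim.deform_rate_vox_per_s} vox/s over "
      f"{max(t.timestamp_s for t in res.tiles):.0f} s of acquisition")

nonrigid = res.stitched
rigid = stitch_tiles(res.tiles, cfg, non_rigid=False,
                     std_threshold=0.25 * res.phantom.mu_tissue)
rms_n = np.sqrt((nonrigid.std_map[nonrigid.overlap_mask] ** 2).mean())
rms_r = np.sqrt((rigid.std_map[rigid.overlap_mask] ** 2).mean())
print(f"overlap mismatch (std-map RMS): rigid {rms_r:.0f} /m, "
      f"non-rigid {rms_n:.0f} /m "
      f"({100 * (1 - rms_n / rms_r):.0f}% lower with local warping)")
print(f"artifact volume fraction (std above threshold): "
      f"non-rigid {nonrigid.report['artifact_fraction']:.4f}, "
      f"rigid {rigid.report['artifact_fraction']:.4f}")
for p in nonrigid.report["pairs"]:
    print(f"  pair {p['a']} -> {p['b']}: NCC {p['score']:.3f}, "
          f"{p.get('n_valid_points', 0)} matched control points")
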